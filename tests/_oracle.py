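"""Straight-line per-gene reimplementation of the cascade criteria.

Deliberately naive: plain Python loops, scipy's reference t-test, and the
three printed decision rules written out gene by gene. Used as an
independent oracle against the vectorized pipeline.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from contactnorm import CascadeConfig, StudyDesign


def naive_p(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=True).pvalue)


def naive_cascade(tpm, design: StudyDesign, config: CascadeConfig | None = None):
    """Return {gene_id: layer} by applying the three criteria one gene at a time."""
    cfg = config or CascadeConfig()
    pc = cfg.pseudocount
    layers = {}
    reps = {g: design.samples_in(g) for g in
            ("N_self", "T_self", "T_vs_N", "T_vs_KO")}
    for gene in tpm.index:
        row = tpm.loc[gene]
        vals = {g: [row[s] for s in samples] for g, samples in reps.items()}
        means = {g: float(np.mean(v)) for g, v in vals.items()}

        if not any(m >= cfg.min_tpm for m in means.values()):
            layers[gene] = "not_expressed"
            continue

        src_fc = (means["T_self"] + pc) / (means["N_self"] + pc)
        src_p = naive_p(vals["T_self"], vals["N_self"])
        if src_fc >= cfg.src_fold and src_p < cfg.src_alpha:
            src_class = "up"
        elif src_fc <= 1.0 / cfg.src_fold and src_p < cfg.src_alpha:
            src_class = "down"
        else:
            layers[gene] = "expressed_unaffected"
            continue

        change = (means["T_vs_N"] - means["T_self"]) / (means["T_self"] + pc)
        rev_p = naive_p(vals["T_self"], vals["T_vs_N"])
        opposite = change <= -cfg.reversal_fraction if src_class == "up" \
            else change >= cfg.reversal_fraction
        if not (opposite and rev_p < cfg.reversal_alpha):
            layers[gene] = "src_only"
            continue

        cdh_fc = (means["T_vs_KO"] + pc) / (means["T_vs_N"] + pc)
        cdh_p = naive_p(vals["T_vs_N"], vals["T_vs_KO"])
        toward_src = cdh_fc >= cfg.cdh_fold if src_class == "up" \
            else cdh_fc <= 1.0 / cfg.cdh_fold
        if toward_src and cdh_p < cfg.cdh_alpha:
            layers[gene] = "cn_cadherin_dependent"
        else:
            layers[gene] = "cn_cadherin_independent"
    return layers
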
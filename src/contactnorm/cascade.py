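"""The three-stage "onion" classification of contact-normalized genes.

Stage 1 (Src effect): transformed-self vs normal-self, fold change at least
``src_fold`` (default 3) in either direction with t-test p below
``src_alpha`` (default 0.05).

Stage 2 (reversal by contact normalization): among Src-affected genes,
coculture with cadherin-competent nontransformed cells moves expression in
the direction opposite the Src effect by at least ``reversal_fraction``
(default 0.40) of the transformed-self level, p below ``reversal_alpha``
(default 0.08).

Stage 3 (cadherin dependence): among reversed genes, the cadherin-knockout
coculture differs from the competent coculture by at least ``cdh_fold``
(default 2) in the direction that undoes normalization (back toward the
transformed-self level), p below ``cdh_alpha`` (default 0.05).

All "up"/"down" suffixes in outputs refer to the direction of the Src
effect: ``reversed_down`` counts Src-up genes suppressed by contact, and
``dependent_up`` counts Src-up genes whose suppression required cadherin.
Ties at every fold or fraction threshold are inclusive ("at least").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, fields
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .design import GROUPS, StudyDesign
from .io import ExpressionMatrix
from .quantify import expression_filter, group_means, tpm_normalize, _tpm_frame
from .stats import bh_adjust, fold_change_arrays, pooled_t_arrays

logger = logging.getLogger(__name__)

LAYERS: tuple[str, ...] = (
    "not_expressed",
    "expressed_unaffected",
    "src_only",
    "cn_cadherin_independent",
    "cn_cadherin_dependent",
)

MatrixLike = Union[ExpressionMatrix, pd.DataFrame]


@dataclass
class CascadeConfig:
    """All thresholds of the classification cascade.

    Attributes
    ----------
    min_tpm:
        Expression filter threshold in TPM (inclusive).
    src_fold, src_alpha:
        Minimum Src-effect fold change and its p cut-off.
    reversal_fraction, reversal_alpha:
        Minimum inverse change (fraction of the transformed-self level) and
        its p cut-off. The 0.08 default is deliberately looser than the
        other stages.
    cdh_fold, cdh_alpha:
        Minimum knockout-vs-competent coculture differential and p cut-off.
    pseudocount:
        Additive stabilizer (TPM units) in every ratio denominator and
        numerator.
    filter_scope:
        ``"group_mean"`` (default) or ``"any_sample"``; see
        :func:`contactnorm.quantify.expression_filter`.
    reversal_mode:
        ``"relative"`` (default): change measured relative to the
        transformed-self level. ``"restoration"``: change measured as the
        fraction of the gap back toward the normal-self baseline that the
        coculture closes.
    log_scale_tests:
        When True, t-tests run on log2(TPM + 1) replicate values instead of
        raw TPM. Fold changes always use raw group means.
    bh_correct:
        When True, stage p-values are Benjamini-Hochberg adjusted across the
        genes tested at that stage before comparison with the alpha.
    """

    min_tpm: float = 1.0
    src_fold: float = 3.0
    src_alpha: float = 0.05
    reversal_fraction: float = 0.40
    reversal_alpha: float = 0.08
    cdh_fold: float = 2.0
    cdh_alpha: float = 0.05
    pseudocount: float = 1.0
    filter_scope: str = "group_mean"
    reversal_mode: str = "relative"
    log_scale_tests: bool = False
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if self.src_fold < 1 or self.cdh_fold < 1:
            raise ValueError("fold thresholds must be >= 1")
        for name in ("src_alpha", "reversal_alpha", "cdh_alpha"):
            a = getattr(self, name)
            if not 0 <= a <= 1:  # 0 is a valid degenerate cut-off: nothing passes
                raise ValueError(f"{name} must be in [0, 1], got {a}")
        if not 0 < self.reversal_fraction < 1:
            raise ValueError("reversal_fraction must be in (0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.min_tpm < 0:
            raise ValueError("min_tpm must be non-negative")
        if self.filter_scope not in ("group_mean", "any_sample"):
            raise ValueError(f"unknown filter_scope {self.filter_scope!r}")
        if self.reversal_mode not in ("relative", "restoration"):
            raise ValueError(f"unknown reversal_mode {self.reversal_mode!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "CascadeConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(
                f"unknown cascade option(s) {sorted(unknown)}; known: {sorted(known)}"
            )
        return cls(**mapping)  # type: ignore[arg-type]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CascadeResult:
    """Per-gene classification table plus onion-layer counts."""

    per_gene: pd.DataFrame
    summary: dict
    config: CascadeConfig


def _replicate_values(tpm: pd.DataFrame, design: StudyDesign, group: str,
                      genes: pd.Index, log_scale: bool) -> np.ndarray:
    samples = design.samples_in(group)
    if len(samples) < 2:
        raise ValueError(f"group {group!r} needs >= 2 replicates")
    vals = tpm.loc[genes, samples].to_numpy(dtype=float)
    return np.log2(vals + 1.0) if log_scale else vals


def _stage_p(p: np.ndarray, config: CascadeConfig) -> np.ndarray:
    return bh_adjust(p) if (config.bh_correct and p.size) else p


def classify_src_effect(
    tpm: MatrixLike,
    design: StudyDesign,
    config: CascadeConfig | None = None,
    genes: pd.Index | None = None,
) -> pd.DataFrame:
    """Stage 1: transformed-self vs normal-self fold change and t-test.

    Returns a frame with ``src_fc`` (T_self over N_self, pseudocount
    stabilized), ``src_p`` and ``src_class`` in {up, down, none}.
    """
    config = config or CascadeConfig()
    values = _tpm_frame(tpm)
    design.require_groups(["N_self", "T_self"])
    genes = values.index if genes is None else genes
    means = group_means(values.loc[genes], design)
    fc = fold_change_arrays(means["T_self"].to_numpy(), means["N_self"].to_numpy(),
                            config.pseudocount)
    a = _replicate_values(values, design, "T_self", genes, config.log_scale_tests)
    b = _replicate_values(values, design, "N_self", genes, config.log_scale_tests)
    _, p = pooled_t_arrays(a, b)
    p = _stage_p(p, config)
    cls = np.where((fc >= config.src_fold) & (p < config.src_alpha), "up",
                   np.where((fc <= 1.0 / config.src_fold) & (p < config.src_alpha),
                            "down", "none"))
    return pd.DataFrame({"src_fc": fc, "src_p": p, "src_class": cls}, index=genes)


def classify_reversal(
    tpm: MatrixLike,
    design: StudyDesign,
    config: CascadeConfig | None = None,
    src_classes: pd.Series | None = None,
) -> pd.DataFrame:
    """Stage 2: contact-normalization reversal among Src-affected genes.

    ``src_classes`` must hold 'up'/'down' for every gene to test; genes that
    did not pass stage 1 are rejected. Returns ``reversal_change`` (signed,
    mode-dependent), ``reversal_p`` and the boolean ``reversed``.
    """
    config = config or CascadeConfig()
    if src_classes is None or len(src_classes) == 0:
        raise ValueError("classify_reversal requires the stage-1 classes of the genes to test")
    bad = set(src_classes.unique()) - {"up", "down"}
    if bad:
        raise ValueError(
            f"classify_reversal applies only to Src-affected genes; got class(es) {sorted(bad)}"
        )
    values = _tpm_frame(tpm)
    design.require_groups(["T_self", "T_vs_N"])
    genes = src_classes.index
    means = group_means(values.loc[genes], design)
    m_t = means["T_self"].to_numpy()
    m_c = means["T_vs_N"].to_numpy()
    up = (src_classes == "up").to_numpy()
    if config.reversal_mode == "relative":
        change = (m_c - m_t) / (m_t + config.pseudocount)
        magnitude_ok = np.where(up, change <= -config.reversal_fraction,
                                change >= config.reversal_fraction)
    else:  # restoration toward the normal-self baseline
        design.require_groups(["N_self"])
        m_n = means["N_self"].to_numpy()
        gap = m_n - m_t
        with np.errstate(divide="ignore", invalid="ignore"):
            change = np.where(gap != 0, (m_c - m_t) / np.where(gap != 0, gap, 1.0), 0.0)
        magnitude_ok = change >= config.reversal_fraction
    a = _replicate_values(values, design, "T_self", genes, config.log_scale_tests)
    b = _replicate_values(values, design, "T_vs_N", genes, config.log_scale_tests)
    _, p = pooled_t_arrays(a, b)
    p = _stage_p(p, config)
    rev = magnitude_ok & (p < config.reversal_alpha)
    return pd.DataFrame(
        {"reversal_change": change, "reversal_p": p, "reversed": rev}, index=genes
    )


def classify_cadherin_dependence(
    tpm: MatrixLike,
    design: StudyDesign,
    config: CascadeConfig | None = None,
    src_classes: pd.Series | None = None,
) -> pd.DataFrame:
    """Stage 3: knockout vs competent coculture differential among reversed genes.

    A gene is cadherin *dependent* when removing cadherin from the
    nontransformed neighbors moves expression back toward the
    transformed-self direction by at least ``cdh_fold`` (up for Src-up
    genes, down for Src-down genes) with p below ``cdh_alpha``. A
    differential in the inconsistent direction does not count as loss of
    normalization; the gene stays *independent*.

    ``src_classes`` carries the stage-1 direction of each reversed gene.
    """
    config = config or CascadeConfig()
    if src_classes is None or len(src_classes) == 0:
        raise ValueError(
            "classify_cadherin_dependence requires the Src direction of the reversed genes"
        )
    bad = set(src_classes.unique()) - {"up", "down"}
    if bad:
        raise ValueError(
            f"classify_cadherin_dependence applies only to reversed genes; got {sorted(bad)}"
        )
    values = _tpm_frame(tpm)
    design.require_groups(["T_vs_N", "T_vs_KO"])
    genes = src_classes.index
    means = group_means(values.loc[genes], design)
    fc = fold_change_arrays(means["T_vs_KO"].to_numpy(), means["T_vs_N"].to_numpy(),
                            config.pseudocount)
    up = (src_classes == "up").to_numpy()
    direction_ok = np.where(up, fc >= config.cdh_fold, fc <= 1.0 / config.cdh_fold)
    a = _replicate_values(values, design, "T_vs_N", genes, config.log_scale_tests)
    b = _replicate_values(values, design, "T_vs_KO", genes, config.log_scale_tests)
    _, p = pooled_t_arrays(a, b)
    p = _stage_p(p, config)
    cls = np.where(direction_ok & (p < config.cdh_alpha), "dependent", "independent")
    return pd.DataFrame({"cdh_fc": fc, "cdh_p": p, "cdh_class": cls}, index=genes)


def onion_summary(per_gene: pd.DataFrame) -> dict:
    """Layer counts in the nested onion structure (up/down = Src direction)."""
    layer = per_gene["layer"]
    src = per_gene["src_class"]
    rev = per_gene["reversed"] == True  # noqa: E712 — object column with NaN
    dep = per_gene["cdh_class"] == "dependent"
    return {
        "detected": int(len(per_gene)),
        "expressed": int((layer != "not_expressed").sum()),
        "src_up": int((src == "up").sum()),
        "src_down": int((src == "down").sum()),
        "reversed_up": int(((src == "up") & rev).sum()),
        "reversed_down": int(((src == "down") & rev).sum()),
        "dependent_up": int(((src == "up") & dep).sum()),
        "dependent_down": int(((src == "down") & dep).sum()),
    }


def run_cascade(
    matrix: MatrixLike,
    design: StudyDesign,
    config: CascadeConfig | None = None,
) -> CascadeResult:
    """Run filter -> Src effect -> reversal -> cadherin dependence.

    ``matrix`` may be a counts :class:`ExpressionMatrix` (normalized to TPM
    internally), a TPM-flagged one, or a plain TPM DataFrame.

    The per-gene table partitions every detected gene into exactly one
    layer; statistics of stages a gene never reached are NaN, and
    ``cdh_class`` is ``not_applicable`` for expressed genes that were not
    reversed.
    """
    config = config or CascadeConfig()
    if isinstance(matrix, ExpressionMatrix) and matrix.units == "counts":
        matrix = tpm_normalize(matrix)
    tpm = _tpm_frame(matrix)
    design.require_groups(GROUPS)

    kept, means = expression_filter(tpm, design, config.min_tpm, config.filter_scope)
    logger.info("expression filter: %d of %d genes at TPM >= %g (%s)",
                len(kept), len(tpm), config.min_tpm, config.filter_scope)

    per_gene = means.add_prefix("mean_")
    per_gene["src_fc"] = np.nan
    per_gene["src_p"] = np.nan
    per_gene["src_class"] = pd.Series(np.nan, index=tpm.index, dtype=object)
    per_gene["reversal_change"] = np.nan
    per_gene["reversal_p"] = np.nan
    per_gene["reversed"] = pd.Series(np.nan, index=tpm.index, dtype=object)
    per_gene["cdh_fc"] = np.nan
    per_gene["cdh_p"] = np.nan
    per_gene["cdh_class"] = pd.Series(np.nan, index=tpm.index, dtype=object)
    per_gene["layer"] = "not_expressed"

    if len(kept):
        src = classify_src_effect(tpm, design, config, genes=kept)
        per_gene.loc[kept, ["src_fc", "src_p", "src_class"]] = src
        per_gene.loc[kept, "layer"] = "expressed_unaffected"
        per_gene.loc[kept, "reversed"] = False
        per_gene.loc[kept, "cdh_class"] = "not_applicable"
        affected = src.index[src["src_class"] != "none"]
        logger.info("Src effect: %d genes at fold >= %g, p < %g",
                    len(affected), config.src_fold, config.src_alpha)
        if len(affected):
            per_gene.loc[affected, "layer"] = "src_only"
            rev = classify_reversal(tpm, design, config,
                                    src_classes=src.loc[affected, "src_class"])
            per_gene.loc[affected, ["reversal_change", "reversal_p", "reversed"]] = rev
            reversed_genes = rev.index[rev["reversed"]]
            logger.info("reversal: %d genes at |change| >= %g, p < %g",
                        len(reversed_genes), config.reversal_fraction,
                        config.reversal_alpha)
            if len(reversed_genes):
                per_gene.loc[reversed_genes, "layer"] = "cn_cadherin_independent"
                cdh = classify_cadherin_dependence(
                    tpm, design, config,
                    src_classes=src.loc[reversed_genes, "src_class"])
                per_gene.loc[reversed_genes, ["cdh_fc", "cdh_p", "cdh_class"]] = cdh
                dependent = cdh.index[cdh["cdh_class"] == "dependent"]
                per_gene.loc[dependent, "layer"] = "cn_cadherin_dependent"
                logger.info("cadherin dependence: %d genes at fold >= %g, p < %g",
                            len(dependent), config.cdh_fold, config.cdh_alpha)

    summary = onion_summary(per_gene)
    return CascadeResult(per_gene=per_gene, summary=summary, config=config)


class ContactNormalizationCascade(ClusterMixin, BaseEstimator):
    """Estimator interface to the onion-layer cascade.

    Rows of ``X`` are genes (the objects being labeled) and columns are the
    twelve layered-culture samples; ``design`` maps columns to the four
    study groups. After ``fit``, ``labels_`` holds one onion layer per gene.

    Examples
    --------
    >>> cascade = ContactNormalizationCascade(design=design)
    >>> layers = cascade.fit_predict(tpm)      # doctest: +SKIP
    >>> cascade.summary_["src_up"]             # doctest: +SKIP
    """

    def __init__(
        self,
        design: Optional[StudyDesign] = None,
        min_tpm: float = 1.0,
        src_fold: float = 3.0,
        src_alpha: float = 0.05,
        reversal_fraction: float = 0.40,
        reversal_alpha: float = 0.08,
        cdh_fold: float = 2.0,
        cdh_alpha: float = 0.05,
        pseudocount: float = 1.0,
        filter_scope: str = "group_mean",
        reversal_mode: str = "relative",
        log_scale_tests: bool = False,
        bh_correct: bool = False,
    ):
        self.design = design
        self.min_tpm = min_tpm
        self.src_fold = src_fold
        self.src_alpha = src_alpha
        self.reversal_fraction = reversal_fraction
        self.reversal_alpha = reversal_alpha
        self.cdh_fold = cdh_fold
        self.cdh_alpha = cdh_alpha
        self.pseudocount = pseudocount
        self.filter_scope = filter_scope
        self.reversal_mode = reversal_mode
        self.log_scale_tests = log_scale_tests
        self.bh_correct = bh_correct

    def _config(self) -> CascadeConfig:
        params = self.get_params()
        params.pop("design")
        return CascadeConfig(**params)

    def fit(self, X: MatrixLike, y=None) -> "ContactNormalizationCascade":
        if self.design is None:
            raise ValueError("a StudyDesign is required (design=...)")
        result = run_cascade(X, self.design, self._config())
        self.classification_ = result.per_gene
        self.summary_ = result.summary
        self.labels_ = result.per_gene["layer"].to_numpy()
        frame = X.values if isinstance(X, ExpressionMatrix) else pd.DataFrame(X)
        self.n_features_in_ = frame.shape[1]
        return self
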
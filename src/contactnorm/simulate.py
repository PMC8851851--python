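"""Synthetic count data with planted onion-layer ground truth.

The generator emulates the four-group layered-culture design (default three
replicates per group) with a gamma-Poisson (negative-binomial) count model:
each gene carries a planted class that fixes its expected TPM in the four
groups, expected TPMs are converted to expected counts through per-gene
lengths and jittered per-sample library sizes, and counts are drawn with a
per-gene dispersion shared across groups. Dispersion exactly 0 yields
deterministic rounded expected counts.

Planted classes (up/down is the direction of the Src effect):

* ``unaffected`` — same mean in all four groups.
* ``src_up`` / ``src_down`` — transformed-self shifted by ``src_fold``; the
  cocultures stay at the transformed-self level.
* ``reversed_independent_up`` / ``_down`` — the competent coculture removes
  (adds) ``reversal_fraction`` of the transformed-self level; the knockout
  coculture matches the competent one.
* ``reversed_dependent_up`` / ``_down`` — as above, but the knockout
  coculture moves back toward the transformed-self direction by
  ``cdh_fold``.
* ``not_expressed`` — mean below the expression filter in every group.

Per-gene random substreams are derived from the root seed, so appending
genes to a specification never perturbs the counts of earlier genes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import GROUPS, StudyDesign
from .io import ExpressionMatrix, write_lengths

CLASS_LABELS: tuple[str, ...] = (
    "unaffected",
    "src_up",
    "src_down",
    "reversed_independent_up",
    "reversed_independent_down",
    "reversed_dependent_up",
    "reversed_dependent_down",
    "not_expressed",
)

#: onion layer the cascade should assign to each planted class
LAYER_OF_CLASS: dict[str, str] = {
    "unaffected": "expressed_unaffected",
    "src_up": "src_only",
    "src_down": "src_only",
    "reversed_independent_up": "cn_cadherin_independent",
    "reversed_independent_down": "cn_cadherin_independent",
    "reversed_dependent_up": "cn_cadherin_dependent",
    "reversed_dependent_down": "cn_cadherin_dependent",
    "not_expressed": "not_expressed",
}

_STAGES = ("expression", "src_effect", "reversal", "cadherin_dependence")


@dataclass(frozen=True)
class PlantedGeneSpec:
    """Planted class and effect sizes for one gene (or a block of genes).

    ``base_mean`` is the expected TPM-scale expression in the normal-self
    group; ``src_fold`` the multiplicative Src effect; ``reversal_fraction``
    the fraction of the Src-alone level removed (Src-up genes) or added
    (Src-down genes) under competent coculture; ``cdh_fold`` the
    knockout-vs-competent differential for dependent classes; ``dispersion``
    the gamma-Poisson dispersion.
    """

    class_label: str
    base_mean: float = 100.0
    src_fold: float = 8.0
    reversal_fraction: float = 0.6
    cdh_fold: float = 4.0
    dispersion: float = 0.01

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"unknown class label {self.class_label!r}; expected one of {CLASS_LABELS}"
            )
        if self.base_mean < 0:
            raise ValueError("base_mean must be non-negative")
        if self.src_fold < 1:
            raise ValueError("src_fold must be >= 1")
        if self.cdh_fold < 1:
            raise ValueError("cdh_fold must be >= 1")
        if self.class_label.endswith("_up") and not 0 <= self.reversal_fraction <= 1:
            raise ValueError("reversal_fraction must be in [0, 1] for *_up classes")
        if self.reversal_fraction < 0:
            raise ValueError("reversal_fraction must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")

    def group_means(self) -> np.ndarray:
        """Expected TPM-scale mean in each of the four groups (GROUPS order)."""
        b = self.base_mean
        label = self.class_label
        if label in ("unaffected", "not_expressed"):
            return np.array([b, b, b, b], dtype=float)
        up = label.endswith("_up")
        t = b * self.src_fold if up else b / self.src_fold
        if label in ("src_up", "src_down"):
            return np.array([b, t, t, t], dtype=float)
        c = t * (1.0 - self.reversal_fraction) if up else t * (1.0 + self.reversal_fraction)
        if "independent" in label:
            ko = c
        else:
            ko = c * self.cdh_fold if up else c / self.cdh_fold
        return np.array([b, t, c, ko], dtype=float)


@dataclass
class SyntheticDataset:
    """Counts, lengths, design and ground truth of one simulated study."""

    counts: pd.DataFrame
    lengths: pd.Series
    design: StudyDesign
    truth: pd.DataFrame
    seed: int

    def to_expression_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(self.counts, lengths=self.lengths, units="counts")

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_expression_matrix().write(out / "counts.tsv")
        write_lengths(self.lengths, out / "lengths.tsv")
        self.design.write(out / "design.tsv")
        truth = self.truth.copy()
        truth.index.name = "gene_id"
        truth.to_csv(out / "truth.tsv", sep="\t")


def generate_dataset(
    specs: Sequence[tuple[PlantedGeneSpec, int]],
    replicates: int = 3,
    library_size: float = 2e7,
    seed: int = 0,
    lengths: pd.Series | None = None,
) -> SyntheticDataset:
    """Draw a counts table with planted per-gene classes.

    Parameters
    ----------
    specs:
        ``(spec, n_genes)`` pairs; each spec is replicated ``n_genes`` times.
    replicates:
        Samples per group (>= 2; the study design uses 3).
    library_size:
        Expected reads per sample; realized per-sample depths are jittered
        uniformly within +-10% to exercise TPM's per-sample normalization.
    lengths:
        Optional per-gene lengths; drawn uniformly from [500, 5000] bases
        when omitted.

    Notes
    -----
    Planted means are TPM-scale: after per-sample normalization the realized
    expected TPM of gene g in group k is ``mean_gk * 1e6 / sum_g(mean_gk)``.
    The mix helpers pick the base level so planted normal-self means total
    one million, making planted values (including the sub-threshold means of
    ``not_expressed`` genes) realized TPMs up to the modest compositional
    shift in the perturbed groups.
    """
    if not specs:
        raise ValueError("at least one planted gene spec is required")
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    per_gene: list[PlantedGeneSpec] = []
    for spec, n in specs:
        if n < 1:
            raise ValueError("each spec needs n_genes >= 1")
        per_gene.extend([spec] * n)
    n_genes = len(per_gene)
    gene_ids = [f"G{i:06d}" for i in range(1, n_genes + 1)]

    sample_ids = [f"{g}_{r + 1}" for g in GROUPS for r in range(replicates)]
    design = StudyDesign({s: g for g in GROUPS for s in
                          (f"{g}_{r + 1}" for r in range(replicates))})
    group_index = np.repeat(np.arange(len(GROUPS)), replicates)

    # dedicated substreams: (0,) sample-level jitter, (1, i) per gene, (2,) lengths
    sample_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    lib_sizes = library_size * sample_rng.uniform(0.9, 1.1, size=len(sample_ids))
    if lengths is None:
        length_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
        lengths = pd.Series(
            length_rng.integers(500, 5001, size=n_genes).astype(float), index=gene_ids
        )
    else:
        if len(lengths) != n_genes:
            raise ValueError(f"expected {n_genes} lengths, got {len(lengths)}")
        lengths = pd.Series(np.asarray(lengths, dtype=float), index=gene_ids)

    mean_tpm = np.stack([s.group_means() for s in per_gene])  # genes x 4
    weights = mean_tpm * lengths.to_numpy()[:, None]
    # anchor read mass to the normal-self group: one global constant keeps
    # every planted within-gene ratio exact on the count scale, and TPM's
    # per-sample normalization is unaffected by per-sample depth anyway
    anchor = weights[:, 0].sum()
    if anchor <= 0:
        raise ValueError("planted means are all zero in the normal-self group")
    mu = (weights / anchor)[:, group_index] * lib_sizes[None, :]  # genes x samples

    counts = np.empty((n_genes, len(sample_ids)), dtype=np.int64)
    for i, spec in enumerate(per_gene):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, i)))
        d = spec.dispersion
        row = mu[i]
        if d == 0:
            counts[i] = np.rint(row).astype(np.int64)
        else:
            lam = rng.gamma(shape=1.0 / d, scale=row * d)
            counts[i] = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    truth = pd.DataFrame([asdict(s) for s in per_gene], index=gene_ids)
    return SyntheticDataset(counts=counts_df, lengths=lengths, design=design,
                            truth=truth, seed=seed)


def _build_mix(blocks, base_mean, low_mean, src_fold, reversal_fraction,
               cdh_fold, dispersion) -> list[tuple[PlantedGeneSpec, int]]:
    if base_mean is None:
        # planted means are realized as TPM after per-sample normalization,
        # so choose the expressed base level to make the normal-self group
        # total ~1e6: base_mean is then directly comparable to min_tpm
        n_expressed = sum(n for label, n in blocks if label != "not_expressed")
        n_low = sum(n for label, n in blocks if label == "not_expressed")
        base_mean = (1e6 - n_low * low_mean) / n_expressed
    out = []
    for label, n in blocks:
        spec = PlantedGeneSpec(
            class_label=label,
            base_mean=low_mean if label == "not_expressed" else base_mean,
            src_fold=src_fold,
            reversal_fraction=reversal_fraction,
            cdh_fold=cdh_fold,
            dispersion=dispersion,
        )
        out.append((spec, n))
    return out


def study_mix(
    scale: float = 1.0,
    src_fold: float = 8.0,
    reversal_fraction: float = 0.6,
    cdh_fold: float = 4.0,
    dispersion: float = 0.01,
    base_mean: float | None = None,
    low_mean: float = 0.1,
) -> list[tuple[PlantedGeneSpec, int]]:
    """Planted class mix mirroring the study's onion-layer proportions.

    At ``scale=1`` the mix plants 49,315 genes of which 21,738 are expressed,
    3,391 Src-affected (2,240 up / 1,151 down), 654 reversed (328 Src-up /
    326 Src-down) and 84 cadherin-dependent (16 Src-up / 68 Src-down) —
    the nested counts of the study's transcriptome. ``scale`` shrinks every
    block (minimum one gene) for desk-scale runs. When ``base_mean`` is
    omitted it is set so the planted normal-self TPMs total one million,
    which makes planted values realized TPMs.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    blocks = [
        ("not_expressed", 27_577),
        ("unaffected", 18_347),
        ("src_up", 1_912),
        ("src_down", 825),
        ("reversed_independent_up", 312),
        ("reversed_independent_down", 258),
        ("reversed_dependent_up", 16),
        ("reversed_dependent_down", 68),
    ]
    blocks = [(label, max(1, round(n * scale))) for label, n in blocks]
    return _build_mix(blocks, base_mean, low_mean, src_fold,
                      reversal_fraction, cdh_fold, dispersion)


def recovery_benchmark_mix(
    src_fold: float = 8.0,
    reversal_fraction: float = 0.6,
    cdh_fold: float = 4.0,
    dispersion: float = 0.01,
    base_mean: float | None = None,
    low_mean: float = 0.1,
) -> list[tuple[PlantedGeneSpec, int]]:
    """1,000-gene validation mix with every class well represented.

    Defaults plant effects at twice each default cascade threshold
    (fold 8 vs 3, reversal 0.6 vs 0.4, cadherin differential 4 vs 2) so that
    stage recovery measures the pipeline rather than borderline calls, while
    keeping the Src-affected fraction at 20% of expressed genes so the
    group-level TPM renormalization shift stays realistic.
    """
    blocks = [
        ("not_expressed", 200),
        ("unaffected", 640),
        ("src_up", 40),
        ("src_down", 40),
        ("reversed_independent_up", 20),
        ("reversed_independent_down", 20),
        ("reversed_dependent_up", 20),
        ("reversed_dependent_down", 20),
    ]
    return _build_mix(blocks, base_mean, low_mean, src_fold,
                      reversal_fraction, cdh_fold, dispersion)


@dataclass
class RecoveryReport:
    """Confusion matrix plus per-stage sensitivity/specificity."""

    confusion: pd.DataFrame
    stages: dict[str, dict[str, float]]
    layer_accuracy: float

    def to_dict(self) -> dict:
        return {
            "layer_accuracy": self.layer_accuracy,
            "stages": self.stages,
            "confusion": {
                str(k): {str(c): int(v) for c, v in row.items()}
                for k, row in self.confusion.iterrows()
            },
        }


def _sens_spec(pos_truth: pd.Series, pos_pred: pd.Series,
               universe: pd.Series) -> dict[str, float]:
    pt = pos_truth[universe]
    pp = pos_pred[universe]
    p = int(pt.sum())
    n = int((~pt).sum())
    tp = int((pt & pp).sum())
    tn = int((~pt & ~pp).sum())
    return {
        "sensitivity": tp / p if p else float("nan"),
        "specificity": tn / n if n else float("nan"),
    }


def evaluate_recovery(truth: pd.DataFrame, classification: pd.DataFrame) -> RecoveryReport:
    """Compare cascade output against planted truth.

    Parameters
    ----------
    truth:
        Frame with a ``class_label`` column (as written by the generator).
    classification:
        Per-gene cascade output with a ``layer`` column.

    Each stage's sensitivity/specificity is computed over the genes that
    truly reach that stage: expression over all genes, Src effect over truly
    expressed genes, reversal over truly Src-affected genes, cadherin
    dependence over truly reversed genes.
    """
    if set(truth.index) != set(classification.index):
        raise ValueError("truth and classification cover different gene sets")
    truth = truth.loc[classification.index]
    expected = truth["class_label"].map(LAYER_OF_CLASS)
    predicted = classification["layer"]
    confusion = pd.crosstab(expected.rename("planted"), predicted.rename("assigned"))

    label = truth["class_label"]
    t_expressed = label != "not_expressed"
    t_src = label.isin([
        "src_up", "src_down",
        "reversed_independent_up", "reversed_independent_down",
        "reversed_dependent_up", "reversed_dependent_down",
    ])
    t_rev = label.str.startswith("reversed_")
    t_dep = label.str.startswith("reversed_dependent")

    p_expressed = predicted != "not_expressed"
    p_src = predicted.isin(["src_only", "cn_cadherin_independent", "cn_cadherin_dependent"])
    p_rev = predicted.isin(["cn_cadherin_independent", "cn_cadherin_dependent"])
    p_dep = predicted == "cn_cadherin_dependent"

    everything = pd.Series(True, index=label.index)
    stages = {
        "expression": _sens_spec(t_expressed, p_expressed, everything),
        "src_effect": _sens_spec(t_src, p_src, t_expressed),
        "reversal": _sens_spec(t_rev, p_rev, t_src),
        "cadherin_dependence": _sens_spec(t_dep, p_dep, t_rev),
    }
    accuracy = float((expected == predicted).mean())
    return RecoveryReport(confusion=confusion, stages=stages, layer_accuracy=accuracy)
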
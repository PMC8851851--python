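import pandas as pd
import pytest

from contactnorm import GROUPS, StudyDesign


def make_design(replicates: int = 3) -> StudyDesign:
    return StudyDesign(
        {f"{g}_{r + 1}": g for g in GROUPS for r in range(replicates)}
    )


def frame_from_groups(gene_rows: dict[str, dict[str, list[float]]]) -> pd.DataFrame:
    """Build a genes x samples table from per-group replicate lists.

    ``gene_rows`` maps gene id -> {group: [replicate values]}; every gene
    must provide the same replicate count per group.
    """
    data = {}
    for gene, groups in gene_rows.items():
        row = {}
        for group, values in groups.items():
            for i, v in enumerate(values):
                row[f"{group}_{i + 1}"] = float(v)
        data[gene] = row
    return pd.DataFrame(data).T


@pytest.fixture
def design3() -> StudyDesign:
    return make_design(3)
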
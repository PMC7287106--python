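"""Packaged worked-example inputs.

The chondrosarcoma grade-comparison table lists the 34 miRNAs a nine-sample
conventional central chondrosarcoma cohort (2 Grade I vs 7 Grade II+III)
reported as strongly modulated: per-group mean CPM, the published 2-dp
log2 fold-change, and the published exact-test p / FDR-BH values. The means
serve as inputs to the fold-change arithmetic; the printed log2FC column is
kept only so recomputation can be checked against it.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: group sizes of the cohort behind the table (Grade I, Grade II+III)
CCC_GROUP_SIZES = (2, 7)

#: the three miRNAs whose modulation trend reversed in the external validation
#: cohort, and the seven below its expression threshold
CCC_VALIDATION_OPPOSITE = ("hsa-miR-206", "hsa-miR-133a-3p", "hsa-miR-146a-5p")
CCC_VALIDATION_NOT_EXPRESSED = (
    "hsa-miR-136-5p",
    "hsa-miR-144-3p",
    "hsa-miR-144-5p",
    "hsa-miR-31-3p",
    "hsa-miR-376a-5p",
    "hsa-miR-4284",
    "hsa-miR-489-3p",
)


def load_ccc_grade_table() -> pd.DataFrame:
    """The 34-row published grade-comparison table, indexed by miRNA id."""
    with resources.files("isomirseq.data").joinpath("ccc_grade_comparison.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df.set_index("feature")
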
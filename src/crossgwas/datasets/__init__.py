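"""Small reference datasets bundled with the package.

``load_smr_blood_reference`` returns a published blood-eQTL SMR result table
for ASD-associated common SNPs (26 rows, of which one probe is listed
twice). It is used to validate the package's BH-FDR and Wald machinery
against independently published numbers: de-duplicating by probe id and
BH-adjusting the 25 unique p_SMR values must reproduce the published FDR_BH
column, and two-sided normal p recomputed from b_SMR/se_SMR must match the
published p_SMR.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_smr_blood_reference"]


def load_smr_blood_reference() -> pd.DataFrame:
    """Published blood-eQTL SMR associations (26 rows, Table-2-style schema)."""
    ref = resources.files(__name__) / "smr_blood_reference.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"ProbeChr": str,
                                                  "topSNP_chr": str})
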
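"""Readers and writers for the package's plain-text interchange formats.

Dialects (all headered, comma- or tab-separated):

* contour CSV: ``x_mm,y_mm`` (see :class:`rugosity.contour.Contour`)
* phenotype CSV: ``fruit_id,ri_percent,sensory_level,RF,HD,AD,CH,SF,WSP,ISP,
  CSP,CEL,HEM,bGAL,PG,CX,PME`` — missing values as empty fields
* counts TSV: ``gene`` id, ``gene_length_bp``, then ``<genotype><stage>_r<rep>``
  sample columns (see :class:`rugosity.expression.ExpressionMatrix`)
* Ct CSV: ``gene,sample,replicate,ct_target,ct_reference``
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import InvalidParameterError
from .expression import CtTable
from .synthetic.population import INDICATOR_COLUMNS

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_ct_table",
    "write_ct_table",
]

PHENOTYPE_COLUMNS = ("fruit_id", "ri_percent", "sensory_level", *INDICATOR_COLUMNS)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV; requires at least fruit_id, ri_percent, sensory_level."""
    df = pd.read_csv(path)
    required = {"fruit_id", "ri_percent", "sensory_level"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(
            f"phenotype CSV must contain {sorted(required)}; got {list(df.columns)}"
        )
    return df


def write_phenotypes(table: pd.DataFrame, path) -> None:
    cols = [c for c in PHENOTYPE_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(Path(path), index=False)


def read_ct_table(path, reference_gene: str = "UBI", calibrator: str | None = None) -> CtTable:
    df = pd.read_csv(path)
    if calibrator is None and len(df) > 0:
        calibrator = str(df["sample"].iloc[0])
    return CtTable(data=df, reference_gene=reference_gene, calibrator_sample=calibrator)


def write_ct_table(ct: CtTable, path) -> None:
    ct.data.to_csv(Path(path), index=False)
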
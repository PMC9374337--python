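"""Packaged reference data.

``protein_panel.csv`` is the measured panel of twelve mEos3.2-tagged
constructs expressed in exponentially growing *E. coli*: nine native
cytoplasmic proteins, the free mEos3.2 tag, and two heterologous TrxA
homologs (from *L. lactis* and *H. volcanii*). Columns: construct and
UniProt/FPbase identifiers, number of analyzed cells, native abundance
(copies/cell), loneliness, monomer and tag masses (kDa), oligomeric
state, complex mass (kDa), and the mean ± SD of the center-region
apparent diffusion coefficient (μm²/s) over the analyzed cells. The free
mEos3.2 construct is recorded with ``mw_kda = 0`` and the full tag mass
in ``tag_mw_kda``, so the complex-mass rule applies uniformly.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .scaling import ProteinRecord

__all__ = ["load_protein_panel", "load_protein_records"]


def load_protein_panel() -> pd.DataFrame:
    """Load the reference protein panel as a DataFrame (12 constructs)."""
    with resources.files("smdmap.data").joinpath("protein_panel.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"construct": str})
    df["heterologous"] = df["heterologous"].astype(bool)
    return df


def load_protein_records() -> list[ProteinRecord]:
    """The same panel as a list of :class:`~smdmap.scaling.ProteinRecord`."""
    df = load_protein_panel()
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ProteinRecord(
                name=row.name,
                monomer_mw=float(row.mw_kda),
                tag_mw=float(row.tag_mw_kda),
                oligomeric_state=int(row.oligomeric_state),
                abundance=None if pd.isna(row.abundance) else float(row.abundance),
                loneliness=None if pd.isna(row.loneliness) else float(row.loneliness),
                d_center_mean=float(row.d_mean),
                d_center_sd=float(row.d_sd),
                heterologous=bool(row.heterologous),
            )
        )
    return records
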
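"""Packaged reference data: published per-residue stability parameters.

``yfh1_residue_params.tsv`` transcribes the published per-residue two-state
unfolding parameters (dHm, dSm, dCp, Tm, Tc, all kcal/mol-based, K) and RAD
burial scores of the 68 resolvable backbone amides of the yeast frataxin
homologue Yfh1 (plus the Trp131 side-chain indole), obtained from a
278-313 K 15N-HSQC melting series.  Two rows carry no RAD score (the
C-terminal Gln and the side-chain indole).

The table serves as golden input for self-consistency checks (the printed
Tc must be a zero of the stability curve built from the printed dHm/Tm/dCp)
and for the outlier-shift analysis against the buried-core reference.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .rad import RADRecord
from .thermo import ThermoParams

__all__ = [
    "load_yfh1_reference_table",
    "yfh1_thermo_params",
    "yfh1_rad_records",
    "RAD01_RESIDUES",
    "REPORTED_CONSISTENT_RESIDUES",
    "REPORTED_OUTLIER_RESIDUES",
]

#: Residue numbers with published RAD < 0.1 (the buried-core reporter set).
RAD01_RESIDUES = [88, 130, 131, 132, 142, 150, 151, 158, 159, 161, 166]

#: Residues reported as consistent with the buried-core average curve
#: (unfolding temperatures within 1.5 K on average).
REPORTED_CONSISTENT_RESIDUES = [
    71, 75, 78, 91, 101, 104, 109, 110, 119, 130, 132, 142, 143, 152,
    158, 159, 160, 168,
]

#: Residues reported as outliers (unfolding temperatures off by more than
#: 3 K on average from the buried-core curve).
REPORTED_OUTLIER_RESIDUES = [
    61, 63, 83, 88, 92, 95, 98, 99, 107, 108, 113, 120, 127, 128, 129,
    136, 146, 147, 154, 172, 174,
]


def load_yfh1_reference_table() -> pd.DataFrame:
    """The published Yfh1 per-residue parameter table as a DataFrame."""
    with resources.files("foldstab.data").joinpath(
        "yfh1_residue_params.tsv"
    ).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def yfh1_thermo_params() -> dict[str, ThermoParams]:
    """Published (dHm, Tm, dCp) per residue label, as ThermoParams."""
    df = load_yfh1_reference_table()
    return {
        str(row.residue_label): ThermoParams(
            dH_m=float(row.dH_kcal_mol),
            T_m=float(row.Tm_K),
            dCp=float(row.dCp_kcal_mol_K),
        )
        for row in df.itertuples()
    }


def yfh1_rad_records() -> list[RADRecord]:
    """Published RAD scores as RADRecord list (rows without a score skipped)."""
    df = load_yfh1_reference_table()
    return [
        RADRecord(residue_label=str(row.residue_label), RAD=float(row.RAD))
        for row in df.itertuples()
        if pd.notna(row.RAD)
    ]
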
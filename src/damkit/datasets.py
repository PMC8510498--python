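"""Published dapsone-derivative panel used as the package's worked example.

Dapsone (DDS, 4,4'-diaminodiphenylsulfone) and ten of its imine derivatives
(Schiff bases from 4-substituted benzaldehydes and cinnamaldehyde) were
characterized at the CAM-B3LYP/6-311G(d,p) level; the tables below carry the
published per-compound values — frontier-orbital eigenvalues, vertical
ionization potentials and electron affinities (with the F/Na map anchors and
the BHT / ascorbic-acid standards), and the mean DPPH / FRAP activities.
These printed values are *inputs* to the descriptor and ratio pipelines; the
derived columns (gap, omega powers, DAM indices, ratios) are always
recomputed by the package.
"""

from __future__ import annotations

import pandas as pd

SUBSTITUENTS = {
    "1": "hydrogen",
    "2": "4-hydroxyl",
    "3": "4-methoxy",
    "4": "4-nitro",
    "5": "4-fluoro",
    "6": "4-chloro",
    "7": "4-bromo",
    "8": "4-cyano",
    "9": "4-carboxyl",
    "10": "2-phenylethylen",
}

# compound_id: (HOMO eV, LUMO eV, published gap eV)
_ORBITALS = {
    "1": (-7.82, -0.99, 6.83),
    "2": (-7.42, -0.69, 6.72),
    "3": (-7.37, -1.93, 6.70),
    "4": (-8.33, -2.03, 6.31),
    "5": (-7.52, -0.89, 6.63),
    "6": (-7.96, -1.23, 6.73),
    "7": (-7.54, -1.05, 6.49),
    "8": (-7.66, -1.57, 6.09),
    "9": (-8.05, -1.50, 6.55),
    "10": (-7.43, -1.15, 6.28),
    "DDS": (-7.25, -0.30, 6.95),
    "BHT": (-7.17, 1.23, 8.40),
    "AA": (-8.22, 0.42, 8.64),
}

# compound_id: (I eV, A eV, published omega-, omega+, Ra, Rd)
_DESCRIPTORS = {
    "1": (8.14, 0.64, 5.24, 0.84, 0.37, 1.53),
    "2": (7.84, 0.33, 4.73, 0.65, 0.28, 1.38),
    "3": (7.77, 0.33, 4.69, 0.64, 0.28, 1.37),
    "4": (8.63, 1.65, 6.79, 1.65, 0.71, 1.98),
    "5": (7.98, 0.51, 5.00, 0.75, 0.33, 1.46),
    "6": (8.27, 0.90, 5.60, 1.02, 0.44, 1.63),
    "7": (8.00, 0.71, 5.24, 0.88, 0.38, 1.53),
    "8": (8.14, 1.17, 5.87, 1.22, 0.53, 1.71),
    "9": (8.35, 1.16, 5.97, 1.21, 0.53, 1.74),
    "10": (7.83, 0.80, 5.24, 0.93, 0.40, 1.53),
    "DDS": (7.78, -1.10, 3.48, 0.14, 0.06, 1.01),
    "BHT": (7.63, -1.64, 3.04, 0.05, 0.02, 0.89),
    "AA": (9.06, -1.16, 4.14, 0.19, 0.08, 1.21),
    "F": (21.26, 1.84, 13.86, 2.31, 1.00, 4.04),
    "Na": (5.38, 0.40, 3.43, 0.54, 0.23, 1.00),
}

# compound_id: (mean %capture, SD, published ratio/DDS, ratio/BHT, star code)
_DPPH = {
    "1": (1.5, 1.2, 0.60, 0.017, "ns"),
    "2": (5.8, 0.6, 1.92, 0.064, "**"),
    "3": (3.3, 1.9, 1.32, 0.036, "ns"),
    "4": (0.0, 1.8, 0.00, 0.000, "ns"),
    "5": (1.7, 0.4, 0.68, 0.019, "ns"),
    "6": (0.0, 1.2, 0.00, 0.000, "*"),
    "7": (0.1, 0.5, 0.04, 0.001, "*"),
    "8": (1.6, 1.6, 0.64, 0.018, "ns"),
    "9": (66.2, 0.5, 26.48, 0.730, "***"),
    "10": (4.0, 0.8, 1.60, 0.044, "ns"),
    "DDS": (2.5, 0.3, 1.00, 0.028, ""),
    "BHT": (90.7, 0.3, 36.28, 1.00, ""),
}

# compound_id: (mean %reduction, SD, published ratio/DDS, ratio/AA, star code)
_FRAP = {
    "1": (15.0, 0.7, 0.9, 0.15, "**"),
    "2": (16.9, 1.3, 1.0, 0.17, "ns"),
    "3": (28.4, 0.8, 1.6, 0.28, "***"),
    "4": (40.7, 0.2, 2.4, 0.41, "***"),
    "5": (13.2, 0.3, 0.8, 0.13, "***"),
    "6": (14.5, 0.4, 0.8, 0.15, "***"),
    "7": (19.3, 1.4, 1.1, 0.19, "**"),
    "8": (20.0, 0.8, 1.2, 0.20, "***"),
    "9": (44.8, 0.7, 2.6, 0.45, "***"),
    "10": (39.6, 0.1, 2.3, 0.40, "***"),
    "DDS": (17.3, 0.6, 1.0, 0.17, ""),
    "AA": (100.0, 0.3, 5.8, 1.00, ""),
}

#: Published ordering sentences for the panel (ascending).
PUBLISHED_ORDERINGS = {
    "omega_minus": ["BHT", "DDS", "AA", "3", "2", "5", "1", "7", "10", "6", "8", "9", "4"],
    "omega_plus": ["BHT", "DDS", "AA", "3", "2", "5", "1", "7", "10", "6", "9", "8", "4"],
    "gap": ["8", "10", "4", "7", "9", "5", "3", "2", "6", "1", "DDS"],
}


def load_orbitals(include_published_gap: bool = False) -> pd.DataFrame:
    """Frontier-orbital eigenvalues of the panel (13 compounds, eV).

    With ``include_published_gap`` the published gap column is attached for
    comparison; note three rows of the published table are internally
    inconsistent with their own orbital energies (compounds 2 and 4 by one
    unit in the last printed place, compound 3 by a transcription error in
    its LUMO), so recomputed gaps do not reproduce those three printed cells.
    """
    df = pd.DataFrame(
        [
            {"compound_id": cid, "e_homo": h, "e_lumo": l, "published_gap": g}
            for cid, (h, l, g) in _ORBITALS.items()
        ]
    )
    return df if include_published_gap else df.drop(columns="published_gap")


def load_ia_table(include_published: bool = False) -> pd.DataFrame:
    """Vertical I/A of the panel plus F/Na anchors (15 compounds, eV)."""
    df = pd.DataFrame(
        [
            {
                "compound_id": cid,
                "i_pot": i,
                "e_aff": a,
                "published_omega_minus": wm,
                "published_omega_plus": wp,
                "published_ra": ra,
                "published_rd": rd,
            }
            for cid, (i, a, wm, wp, ra, rd) in _DESCRIPTORS.items()
        ]
    )
    if include_published:
        return df
    return df[["compound_id", "i_pot", "e_aff"]]


def load_assay_means(assay: str, include_published: bool = False) -> pd.DataFrame:
    """Published mean +/- SD percentages for DPPH or FRAP (triplicates)."""
    table = {"DPPH": _DPPH, "FRAP": _FRAP}[assay.upper()]
    ratio_std = "ratio_to_bht" if assay.upper() == "DPPH" else "ratio_to_aa"
    df = pd.DataFrame(
        [
            {
                "compound_id": cid,
                "mean_percent": m,
                "sd_percent": sd,
                "n": 3,
                "published_ratio_to_dds": rp,
                f"published_{ratio_std}": rs,
                "published_code": code,
            }
            for cid, (m, sd, rp, rs, code) in table.items()
        ]
    )
    if include_published:
        return df
    return df[["compound_id", "mean_percent", "sd_percent", "n"]]
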
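"""Table readers/writers for the descriptor and assay pipelines.

Dialect contract: comma- or tab-delimited UTF-8 with a header row (delimiter
autodetected from the header line), decimal points only, and both the ASCII
hyphen-minus and the typographic minus U+2212 accepted as negative signs on
read (ASCII is always emitted on write). Errors name the offending row.
Writers are atomic: output lands under a temporary name and is renamed into
place, so a failure never leaves a partial file.
"""

from __future__ import annotations

import json
import os
import tempfile
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .assay import AssayPanel, AssayReplicate
from .types import CompoundRecord, OrbitalPair, SpeciesEnergies

MINUS_SIGN = "−"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    text = path.read_text(encoding="utf-8").replace(MINUS_SIGN, "-")
    if not text.strip():
        raise ValueError(f"{path}: empty file (header row required)")
    header = text.splitlines()[0]
    sep = "\t" if "\t" in header else ","
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep=sep, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def _parse_float(df_value: str, column: str, row: int, path) -> float:
    try:
        return float(df_value)
    except (TypeError, ValueError):
        raise ValueError(
            f"{path}: row {row}: unparseable number {df_value!r} in column {column!r}"
        ) from None


def _check_unique_ids(ids, path) -> None:
    seen = set()
    for row, cid in enumerate(ids, start=2):
        if cid in seen:
            raise ValueError(f"{path}: row {row}: duplicate compound_id {cid!r}")
        seen.add(cid)


def read_energy_table(path) -> list[SpeciesEnergies]:
    """Read species-energy triples: compound_id, e_neutral, e_cation, e_anion, unit."""
    df = _read_table(path)
    _require_columns(df, ("compound_id", "e_neutral", "e_cation", "e_anion"), path)
    _check_unique_ids(df["compound_id"], path)
    out = []
    for k, rec in enumerate(df.to_dict("records")):
        row = k + 2  # 1-based with header
        unit = str(rec.get("unit", "eV") or "eV")
        try:
            out.append(
                SpeciesEnergies(
                    compound_id=str(rec["compound_id"]),
                    e_neutral=_parse_float(rec["e_neutral"], "e_neutral", row, path),
                    e_cation=_parse_float(rec["e_cation"], "e_cation", row, path),
                    e_anion=_parse_float(rec["e_anion"], "e_anion", row, path),
                    unit=unit,
                )
            )
        except ValueError as err:
            raise ValueError(f"{path}: row {row}: {err}") from None
    return out


def read_orbital_table(path) -> list[OrbitalPair]:
    """Read frontier-orbital pairs: compound_id, homo_eV, lumo_eV."""
    df = _read_table(path)
    _require_columns(df, ("compound_id", "homo_eV", "lumo_eV"), path)
    _check_unique_ids(df["compound_id"], path)
    return [
        OrbitalPair(
            compound_id=str(rec["compound_id"]),
            e_homo=_parse_float(rec["homo_eV"], "homo_eV", k + 2, path),
            e_lumo=_parse_float(rec["lumo_eV"], "lumo_eV", k + 2, path),
        )
        for k, rec in enumerate(df.to_dict("records"))
    ]


def read_descriptor_table(path) -> list[tuple[str, float, float]]:
    """Read direct (compound_id, I_eV, A_eV) triples.

    Validation is staged: rows with I <= A are accepted here and rejected only
    when an omega power is actually computed, so a table can be loaded for
    gap-free bookkeeping.
    """
    df = _read_table(path)
    _require_columns(df, ("compound_id", "I_eV", "A_eV"), path)
    _check_unique_ids(df["compound_id"], path)
    return [
        (
            str(rec["compound_id"]),
            _parse_float(rec["I_eV"], "I_eV", k + 2, path),
            _parse_float(rec["A_eV"], "A_eV", k + 2, path),
        )
        for k, rec in enumerate(df.to_dict("records"))
    ]


def read_assay_table(path) -> dict[str, AssayPanel]:
    """Read replicate absorbances: assay, compound_id, replicate, absorbance, is_control.

    Returns one panel per assay type present; exactly one control compound is
    required per assay.
    """
    df = _read_table(path)
    _require_columns(df, ("assay", "compound_id", "replicate", "absorbance", "is_control"), path)
    panels = {}
    for assay, grp in df.groupby("assay", sort=False):
        replicates, controls = [], []
        for k, rec in grp.iterrows():
            row = k + 2
            replicates.append(
                AssayReplicate(
                    compound_id=str(rec["compound_id"]),
                    replicate_index=int(_parse_float(rec["replicate"], "replicate", row, path)),
                    absorbance=_parse_float(rec["absorbance"], "absorbance", row, path),
                )
            )
            if str(rec["is_control"]).strip() in ("1", "true", "True"):
                controls.append(str(rec["compound_id"]))
        control_ids = sorted(set(controls))
        if len(control_ids) != 1:
            raise ValueError(
                f"{path}: assay {assay!r} needs exactly one control compound, found {control_ids}"
            )
        panels[str(assay)] = AssayPanel(
            assay_type=str(assay), replicates=tuple(replicates), control_id=control_ids[0]
        )
    return panels


def round_half_away(value: float, precision: int) -> float:
    """Round half away from zero (the convention of the printed report tables)."""
    q = Decimal(1).scaleb(-precision)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _atomic_write(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", text=True)
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def records_frame(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Flatten compound records into the canonical report columns."""
    rows = []
    for rec in records:
        d = rec.descriptors
        rows.append(
            {
                "compound_id": rec.compound_id,
                "I": d.i_pot,
                "A": d.e_aff,
                "gap": d.gap,
                "omega_minus": d.omega_minus,
                "omega_plus": d.omega_plus,
                "Ra": rec.dam.ra if rec.dam else None,
                "Rd": rec.dam.rd if rec.dam else None,
                "region_label": rec.dam.region_label if rec.dam else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "compound_id", "I", "A", "gap", "omega_minus", "omega_plus",
            "Ra", "Rd", "region_label",
        ],
    )


def write_descriptor_report(
    records: Sequence[CompoundRecord],
    path,
    fmt: str = "tsv",
    precision: int = 2,
) -> None:
    """Write the descriptor report as TSV or JSON at display precision."""
    df = records_frame(records)
    display = df.copy()
    for col in ("I", "A", "gap", "omega_minus", "omega_plus", "Ra", "Rd"):
        display[col] = [
            "" if v is None or pd.isna(v) else f"{round_half_away(float(v), precision):.{precision}f}"
            for v in df[col]
        ]
    if fmt == "tsv":
        _atomic_write(path, display.fillna("").to_csv(sep="\t", index=False))
    elif fmt == "json":
        payload = [
            {k: (None if pd.isna(v) else v) for k, v in row.items()}
            for row in display.to_dict("records")
        ]
        _atomic_write(path, json.dumps(payload, indent=1) + "\n")
    else:
        raise ValueError(f"unknown output format {fmt!r}")


def write_dam_report(
    records: Sequence[CompoundRecord],
    csv_path,
    plot_path: Optional[str] = None,
    precision: int = 4,
) -> None:
    """Write DAM coordinates (and optionally a scatter plot).

    The CSV carries compound_id, Ra, Rd, region_label; the plot draws unit
    gridlines at the anchor boundaries Ra = 1 and Rd = 1 with metadata
    stripped for byte-deterministic output.
    """
    placed = [r for r in records if r.dam is not None]
    lines = ["compound_id,Ra,Rd,region_label"]
    for rec in placed:
        lines.append(
            f"{rec.compound_id},{round_half_away(rec.dam.ra, precision):.{precision}f},"
            f"{round_half_away(rec.dam.rd, precision):.{precision}f},{rec.dam.region_label}"
        )
    _atomic_write(csv_path, "\n".join(lines) + "\n")

    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        rd = [r.dam.rd for r in placed]
        ra = [r.dam.ra for r in placed]
        ax.scatter(rd, ra, s=24, color="tab:blue")
        for rec in placed:
            ax.annotate(rec.compound_id, (rec.dam.rd, rec.dam.ra), fontsize=7,
                        xytext=(3, 3), textcoords="offset points")
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
        ax.axvline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("Rd (electron donation index)")
        ax.set_ylabel("Ra (electron acceptation index)")
        ax.set_title("Donor-acceptor map")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150, metadata={"Software": None, "CreationDate": None})
        plt.close(fig)


def write_energy_table(records: Sequence[SpeciesEnergies], path) -> None:
    """Write species-energy triples in the canonical dialect (full precision)."""
    lines = ["compound_id,e_neutral,e_cation,e_anion,unit"]
    for e in records:
        lines.append(f"{e.compound_id},{e.e_neutral!r},{e.e_cation!r},{e.e_anion!r},{e.unit}")
    _atomic_write(path, "\n".join(lines) + "\n")


def write_assay_table(panel: AssayPanel, path) -> None:
    """Write a replicate panel in the canonical assay dialect."""
    lines = ["assay,compound_id,replicate,absorbance,is_control"]
    for r in panel.replicates:
        is_ctrl = 1 if r.compound_id == panel.control_id else 0
        lines.append(
            f"{panel.assay_type},{r.compound_id},{r.replicate_index},{r.absorbance!r},{is_ctrl}"
        )
    _atomic_write(path, "\n".join(lines) + "\n")
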
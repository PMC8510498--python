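"""DPPH and FRAP assay statistics.

DPPH radical scavenging (read at 517 nm) is expressed as

    %capture = 100 * (A_control - A_sample) / A_control

against the DPPH reference solution. FRAP ferric reduction (read at 750 nm)
is expressed relative to an ascorbic-acid positive control as

    %reduction = 100 * A_sample / A_control

so the positive control itself reads 100.0 by construction; a
blank-subtracted variant is available through the ``blank`` argument.
Replicate percentages are summarized as mean +/- sample SD (n-1 denominator),
ratio columns divide compound means by the parent-drug and standard means,
and group comparisons run a one-way ANOVA followed by Dunnett many-to-one
tests against the control group (scipy's multivariate-t implementation),
coded ns/*/**/*** at two-sided p thresholds 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SIGNIFICANCE_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

ASSAY_WAVELENGTH_NM = {"DPPH": 517, "FRAP": 750}


@dataclass(frozen=True)
class AssayReplicate:
    """One absorbance reading (dimensionless AU) of one compound."""

    compound_id: str
    replicate_index: int
    absorbance: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "absorbance", float(self.absorbance))
        object.__setattr__(self, "replicate_index", int(self.replicate_index))
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be a positive integer")
        if not math.isfinite(self.absorbance) or self.absorbance < 0:
            raise ValueError(
                f"compound {self.compound_id!r}, replicate {self.replicate_index}: "
                f"absorbance must be finite and nonnegative, got {self.absorbance!r}"
            )


@dataclass(frozen=True)
class AssayPanel:
    """Replicate absorbances for a set of compounds plus the assay control.

    ``control_id`` names the DPPH reference solution (blank) or the FRAP
    positive control (ascorbic acid); it must appear among the replicates.
    """

    assay_type: str
    replicates: tuple
    control_id: str
    wavelength_nm: Optional[int] = None

    def __post_init__(self) -> None:
        if self.assay_type not in ASSAY_WAVELENGTH_NM:
            raise ValueError(f"assay_type must be DPPH or FRAP, got {self.assay_type!r}")
        object.__setattr__(self, "replicates", tuple(self.replicates))
        if self.wavelength_nm is None:
            object.__setattr__(self, "wavelength_nm", ASSAY_WAVELENGTH_NM[self.assay_type])
        ids = {r.compound_id for r in self.replicates}
        if self.control_id not in ids:
            raise ValueError(f"control {self.control_id!r} has no replicates in the panel")
        if not ids:
            raise ValueError("panel has no replicates")

    def absorbances(self, compound_id: str) -> np.ndarray:
        values = [r.absorbance for r in self.replicates if r.compound_id == compound_id]
        if not values:
            raise KeyError(f"compound {compound_id!r} not in panel")
        return np.asarray(values, dtype=float)

    def compound_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.replicates:
            if r.compound_id not in seen:
                seen.append(r.compound_id)
        return seen


@dataclass(frozen=True)
class AssaySummary:
    """Per-compound mean +/- SD of replicate percentages."""

    compound_id: str
    mean_percent: float
    sd_percent: float
    n: int
    significance_code: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd_percent < 0:
            raise ValueError("sd_percent must be nonnegative")


@dataclass(frozen=True)
class RatioRow:
    """A compound's activity relative to the parent drug and to the standard."""

    compound_id: str
    ratio_to_parent: float
    ratio_to_standard: float

    def __post_init__(self) -> None:
        if self.ratio_to_parent < 0 or self.ratio_to_standard < 0:
            raise ValueError("ratios must be nonnegative")


def dpph_percent_capture(
    a_control: float, a_sample: float, clamp_zero: bool = False
) -> float:
    """DPPH radical capture percentage from control and sample absorbance.

    ``clamp_zero`` floors negative results (sample darker than the radical
    blank) at 0, matching how published tables print inactive compounds.
    """
    if not a_control > 0:
        raise ValueError(f"control absorbance must be positive, got {a_control!r}")
    pct = 100.0 * (a_control - a_sample) / a_control
    if clamp_zero and pct < 0:
        return 0.0
    return pct


def frap_percent_reduction(
    a_sample: float, a_positive_control: float, blank: float = 0.0
) -> float:
    """Ferric-reduction percentage relative to the positive control.

    With the default ``blank = 0`` this is the plain absorbance ratio, which
    makes the positive control row read exactly 100. Passing a reagent-blank
    absorbance subtracts it from both readings first.
    """
    denom = a_positive_control - blank
    if not denom > 0:
        raise ValueError(
            f"positive-control absorbance ({a_positive_control!r}) must exceed the blank ({blank!r})"
        )
    return 100.0 * (a_sample - blank) / denom


def panel_percentages(panel: AssayPanel, clamp_zero: bool = False) -> pd.DataFrame:
    """Per-replicate percentages for every non-control compound in a panel.

    DPPH converts each replicate against the mean control absorbance; FRAP
    expresses each replicate relative to the mean positive-control absorbance
    (so the control compound itself averages 100).
    """
    control_mean = float(np.mean(panel.absorbances(panel.control_id)))
    rows = []
    for r in panel.replicates:
        if panel.assay_type == "DPPH":
            if r.compound_id == panel.control_id:
                continue
            pct = dpph_percent_capture(control_mean, r.absorbance, clamp_zero=clamp_zero)
        else:
            pct = frap_percent_reduction(r.absorbance, control_mean)
        rows.append(
            {"compound_id": r.compound_id, "replicate_index": r.replicate_index, "percent": pct}
        )
    return pd.DataFrame(rows, columns=["compound_id", "replicate_index", "percent"])


def summarize(panel: AssayPanel, clamp_zero: bool = False) -> list[AssaySummary]:
    """Mean and sample SD (n-1) of per-replicate percentages, per compound."""
    pct = panel_percentages(panel, clamp_zero=clamp_zero)
    out = []
    for cid, grp in pct.groupby("compound_id", sort=False):
        values = grp["percent"].to_numpy()
        n = len(values)
        if n == 1:
            warnings.warn(
                f"compound {cid!r}: single replicate, SD reported as 0", stacklevel=2
            )
            sd = 0.0
        else:
            sd = float(np.std(values, ddof=1))
        out.append(AssaySummary(compound_id=str(cid), mean_percent=float(np.mean(values)), sd_percent=sd, n=n))
    return out


def ratio_table(
    summaries: Sequence[AssaySummary], parent_id: str, standard_id: str
) -> list[RatioRow]:
    """Each compound's mean percentage relative to parent drug and standard."""
    means = {s.compound_id: s.mean_percent for s in summaries}
    for role, cid in (("parent", parent_id), ("standard", standard_id)):
        if cid not in means:
            raise ValueError(f"{role} compound {cid!r} absent from summaries")
        if means[cid] == 0:
            raise ValueError(f"{role} compound {cid!r} has zero mean; ratios undefined")
    return [
        RatioRow(
            compound_id=s.compound_id,
            ratio_to_parent=s.mean_percent / means[parent_id],
            ratio_to_standard=s.mean_percent / means[standard_id],
        )
        for s in summaries
    ]


def significance_code(p: float) -> str:
    """Map a two-sided p-value to the conventional star code."""
    for threshold, code in SIGNIFICANCE_THRESHOLDS:
        if p < threshold:
            return code
    return "ns"


@dataclass(frozen=True)
class ControlComparison:
    """Result of ANOVA plus Dunnett many-to-one comparisons against a control."""

    anova_f: float
    anova_p: float
    compound_ids: tuple
    p_values: tuple
    codes: tuple
    method: dict = field(default_factory=dict)

    def code_for(self, compound_id: str) -> str:
        return self.codes[self.compound_ids.index(compound_id)]


def compare_to_control(
    groups: dict[str, Iterable[float]],
    control_id: str,
    seed: int = 0,
) -> ControlComparison:
    """One-way ANOVA, then Dunnett comparisons of each group to the control.

    ``groups`` maps compound_id to its replicate percentages. The Dunnett
    p-values are multiplicity-adjusted through the multivariate-t distribution
    (scipy.stats.dunnett); its quasi-Monte-Carlo integration is seeded for
    reproducibility. Star codes use two-sided thresholds 0.05 / 0.01 / 0.001.
    """
    arrays = {cid: np.asarray(list(v), dtype=float) for cid, v in groups.items()}
    if control_id not in arrays:
        raise ValueError(f"control {control_id!r} absent from groups")
    if len(arrays) < 2:
        raise ValueError("need the control plus at least one test group")
    for cid, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {cid!r} has fewer than 2 replicates")

    test_ids = [cid for cid in arrays if cid != control_id]
    anova = stats.f_oneway(*arrays.values())

    rng = np.random.default_rng(seed)
    dunnett = stats.dunnett(
        *(arrays[cid] for cid in test_ids), control=arrays[control_id], rng=rng
    )
    p_values = tuple(float(p) for p in dunnett.pvalue)
    return ControlComparison(
        anova_f=float(anova.statistic),
        anova_p=float(anova.pvalue),
        compound_ids=tuple(test_ids),
        p_values=p_values,
        codes=tuple(significance_code(p) for p in p_values),
        method={
            "anova": "one-way (scipy.stats.f_oneway)",
            "post_hoc": "Dunnett many-to-one, multivariate-t adjusted (scipy.stats.dunnett)",
            "alternative": "two-sided",
            "seed": seed,
        },
    )


def analyze_panel(
    panel: AssayPanel,
    parent_id: Optional[str] = None,
    standard_id: Optional[str] = None,
    clamp_zero: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-panel report: mean +/- SD, ratio columns, significance codes.

    The many-to-one comparisons run against ``parent_id`` when it is present
    in the percentage table, else against the first compound. Returns one row
    per compound that has percentage readings.
    """
    summaries = summarize(panel, clamp_zero=clamp_zero)
    rows = {s.compound_id: {
        "compound_id": s.compound_id,
        "mean_percent": s.mean_percent,
        "sd_percent": s.sd_percent,
        "n": s.n,
    } for s in summaries}

    if parent_id and standard_id:
        for r in ratio_table(summaries, parent_id, standard_id):
            rows[r.compound_id]["ratio_to_parent"] = r.ratio_to_parent
            rows[r.compound_id]["ratio_to_standard"] = r.ratio_to_standard

    pct = panel_percentages(panel, clamp_zero=clamp_zero)
    groups = {
        str(cid): grp["percent"].to_numpy() for cid, grp in pct.groupby("compound_id", sort=False)
    }
    comparison_control = parent_id if parent_id in groups else next(iter(groups))
    if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
        cmp = compare_to_control(groups, comparison_control, seed=seed)
        for cid, code in zip(cmp.compound_ids, cmp.codes):
            rows[cid]["significance_code"] = code
        rows[comparison_control]["significance_code"] = ""
    return pd.DataFrame(list(rows.values()))
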
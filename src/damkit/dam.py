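"""Donor-acceptor map (DAM) construction.

The DAM places each compound at

    Ra = omega_plus  / omega_plus(F)     (electron acceptation index)
    Rd = omega_minus / omega_minus(Na)   (electron donation index)

where fluorine anchors ideal electron acceptance and sodium ideal electron
donation. The unit lines Ra = 1 and Rd = 1 partition the plane into four
regions; low Ra together with low Rd marks a good electron donor (the
antioxidant corner), high Ra with high Rd a good electron acceptor
(antireductant). The anchors enter as (I, A) pairs only — their omega values
are always recomputed at full precision, so the anchors themselves land
exactly on their unit lines.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .descriptors import electroaccepting_power, electrodonating_power
from .types import DAMPoint, GlobalDescriptors, ReferenceSet

#: Anchor (I, A) in eV at the CAM-B3LYP/6-311G(d,p) level used for the
#: dapsone derivative panel: F (acceptor) and Na (donor).
DEFAULT_REFERENCES = ReferenceSet(i_f=21.26, a_f=1.84, i_na=5.38, a_na=0.40)

#: Verbal reading of each region, emitted as annotation only — the labels are
#: geometric, not a pharmacological claim.
REGION_ANNOTATIONS = {
    "donor-donor": "good electron donor (antioxidant character)",
    "donor-acceptor": "donates and accepts below/above anchors (mixed)",
    "acceptor-donor": "weak on both axes (mixed)",
    "acceptor-acceptor": "good electron acceptor (antireductant character)",
}


def region_label(ra: float, rd: float) -> str:
    """Region of the DAM from the unit thresholds.

    First token: accepting character versus F (``acceptor`` iff Ra > 1).
    Second token: donating character versus Na (``donor`` iff Rd < 1 — lower
    electrodonating power donates more readily). A coordinate exactly on an
    anchor line yields the token ``boundary``.
    """
    if ra == 1.0:
        a_tok = "boundary"
    else:
        a_tok = "acceptor" if ra > 1.0 else "donor"
    if rd == 1.0:
        d_tok = "boundary"
    else:
        d_tok = "donor" if rd < 1.0 else "acceptor"
    return f"{a_tok}-{d_tok}"


def dam_indices(d: GlobalDescriptors, ref: ReferenceSet) -> DAMPoint:
    """DAM coordinates of one compound against a reference set."""
    if d.omega_minus is None or d.omega_plus is None:
        raise ValueError(
            f"compound {d.compound_id!r} has no omega values; cannot place on the DAM"
        )
    ra = d.omega_plus / ref.omega_plus_f
    rd = d.omega_minus / ref.omega_minus_na
    return DAMPoint(compound_id=d.compound_id, ra=ra, rd=rd, region_label=region_label(ra, rd))


class DonorAcceptorMap(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer from omega descriptors to DAM coordinates.

    ``fit`` derives the anchor powers omega_plus(F) and omega_minus(Na) from
    the reference (I, A) pairs; ``transform`` maps a descriptor DataFrame
    (columns ``compound_id``, ``omega_minus``, ``omega_plus``) onto ``ra``,
    ``rd`` and ``region_label`` columns.

    Parameters
    ----------
    acceptor_ref, donor_ref : tuple of float
        (I, A) in eV for the acceptor and donor anchors. Defaults are the
        fluorine and sodium values of the dapsone study panel.

    Attributes
    ----------
    omega_plus_acceptor_ : float
        Electroaccepting power of the acceptor anchor, eV.
    omega_minus_donor_ : float
        Electrodonating power of the donor anchor, eV.
    reference_ : ReferenceSet
        The validated anchor set actually used.
    """

    def __init__(
        self,
        acceptor_ref: tuple = (DEFAULT_REFERENCES.i_f, DEFAULT_REFERENCES.a_f),
        donor_ref: tuple = (DEFAULT_REFERENCES.i_na, DEFAULT_REFERENCES.a_na),
        annotate: bool = False,
    ):
        self.acceptor_ref = acceptor_ref
        self.donor_ref = donor_ref
        self.annotate = annotate

    def fit(self, X: Optional[pd.DataFrame] = None, y=None) -> "DonorAcceptorMap":
        i_f, a_f = map(float, self.acceptor_ref)
        i_na, a_na = map(float, self.donor_ref)
        self.reference_ = ReferenceSet(i_f=i_f, a_f=a_f, i_na=i_na, a_na=a_na)
        self.omega_plus_acceptor_ = electroaccepting_power(i_f, a_f, "acceptor-reference")
        self.omega_minus_donor_ = electrodonating_power(i_na, a_na, "donor-reference")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "reference_"):
            raise RuntimeError("DonorAcceptorMap must be fit before transform")
        missing = [c for c in ("compound_id", "omega_minus", "omega_plus") if c not in X.columns]
        if missing:
            raise ValueError(f"descriptor frame is missing columns {missing}")
        out = X.copy()
        out["ra"] = X["omega_plus"] / self.omega_plus_acceptor_
        out["rd"] = X["omega_minus"] / self.omega_minus_donor_
        out["region_label"] = [region_label(ra, rd) for ra, rd in zip(out["ra"], out["rd"])]
        if self.annotate:
            out["region_note"] = [
                REGION_ANNOTATIONS.get(lbl, "on an anchor boundary") for lbl in out["region_label"]
            ]
        return out
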
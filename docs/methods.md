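# Methods

## Descriptor model

The package works in the finite-difference (vertical) picture of conceptual
DFT. Given total energies of the neutral, cationic and anionic species of a
compound, the vertical ionization potential and electron affinity are

    I = E(cation) − E(neutral),      A = E(neutral) − E(anion),

and the electrodonating / electroaccepting powers are the quadratic-model
charge-transfer energies

    ω⁻ = (3I + A)² / (16 (I − A)),   ω⁺ = (I + 3A)² / (16 (I − A)).

Both are nonnegative for any I > A (perfect squares over a positive
denominator) and satisfy the identity ω⁻ − ω⁺ = (I + A)/2 exactly, which the
property suite asserts on random grids to 1e−9 eV. Whether the supplied
energies are vertical (neutral geometry) or adiabatic (relaxed ions) is the
caller's choice; the algebra is identical and the package is agnostic — it
consumes whatever energies are given.

The donor–acceptor map normalizes against atomic anchors: Ra = ω⁺/ω⁺(F) and
Rd = ω⁻/ω⁻(Na). Anchors are stored as (I, A) pairs only and their ω values
are recomputed at full precision, which forces the anchors themselves onto
the unit lines exactly (Ra(F) = Rd(Na) = 1 with no rounding residue). Region
labels are purely geometric: the first token is the accepting character
versus F (acceptor iff Ra > 1), the second the donating character versus Na
(donor iff Rd < 1, since a lower ω⁻ donates more readily); a point exactly on
an anchor line gets the token `boundary`. The verbal reading (donor–donor =
antioxidant corner, acceptor–acceptor = antireductant corner) is emitted only
as an optional annotation column, never hard-coded into any computation.

Default anchors are the panel's published fluorine (I = 21.26, A = 1.84 eV)
and sodium (I = 5.38, A = 0.40 eV) values; both are overridable per run
(`--ref-f/--ref-na`, or the `DonorAcceptorMap` constructor).

## Units, rounding, ties

Energies are accepted in Hartree or eV with an explicit unit tag and
converted with the CODATA factor 27.211386245988 eV/Hartree; all descriptors
are reported in eV. Readers accept both ASCII hyphen-minus and U+2212 and
autodetect comma/tab delimiters; writers emit ASCII and are atomic (a failed
run never leaves a partial file). Display rounding is half-away-from-zero at
a configurable precision (default 2 dp); report comparisons against printed
tables can therefore differ by one unit in the last place when the original
was rounded from full-precision intermediates. Rankings always sort on
full-precision values with exact-tie fallback to lexicographic compound id;
groups tied only at printed precision are reported through the logger. Inputs
with I ≤ A are a hard error at ω computation time (degenerate denominator),
never clamped; the direct-entry reader accepts such rows so tables can be
loaded for bookkeeping, failing only when an ω is actually requested.

## Assay statistics

DPPH %capture = 100·(A_control − A_sample)/A_control against the mean of the
radical-blank replicates; negative values (sample absorbing above the blank)
are kept by default and floored at zero only under `clamp_zero`, matching how
printed tables show inactive compounds. The FRAP protocol's percentage is not
defined by a formula in assay write-ups of this kind; the package uses
%reduction = 100·A_sample/A_positive-control, which fixes the ascorbic-acid
control row at exactly 100, with a blank-subtracted variant behind the
`blank` argument. Percentages are computed per replicate and then summarized
(mean, sample SD with n−1 — the order matters for the SD and is the
documented convention here; whether published SDs were computed this way or
propagated from absorbance SDs is generally unstated). Group comparisons are
one-way ANOVA followed by Dunnett many-to-one tests against the control
group, with multiplicity adjustment via the multivariate-t distribution
(scipy.stats.dunnett, quasi-Monte-Carlo integration seeded per run), coded
ns/*/**/*** at two-sided 0.05/0.01/0.001. The calibration test drives 1000
simulated null panels (4 groups × 3 replicates) and checks the family-wise
rejection rate against the nominal 0.05 within 3 binomial standard deviations.

## Synthetic data

`panel_generate` draws (I, A) uniformly from configurable ranges (defaults
I ∈ [7.5, 9.0], A ∈ [−1.7, 1.7] eV — the spread of the dapsone panel) with a
rejection step enforcing I − A ≥ 0.5 eV, then builds energy triples as
E(cation) = E(neutral) + I, E(anion) = E(neutral) − A around an arbitrary
anchor, so the pipeline must return the hidden targets exactly (asserted to
1e−9 eV for 1000 compounds). It emulates the *algebraic* structure of a
quantum-chemistry panel only: no correlation between I and A, no basis-set or
functional physics, no geometry relaxation — passing round trips validate the
pipeline's bookkeeping and unit handling, not any electronic-structure claim.

`huckel_orbitals` is an independent oracle for the frontier-orbital path:
eigenvalues of αI + βA(adjacency) for closed-shell π systems, checked against
the closed-form spectra of chains (α + 2β cos(kπ/(n+1))) and rings
(α + 2β cos(2πk/n)); benzene's gap is 2|β| exactly. Electron count defaults
to one π electron per center and must be even; a degenerate HOMO simply
reports the shared eigenvalue.

`assay_simulate` links a descriptor to a true activity through an explicit
logistic, true% = max/(1 + exp(±slope·(ω − midpoint))), signed so lower ω⁻
gives higher capture (and higher ω⁺ higher reduction). Defaults (midpoint
5.0 eV, slope 1.5 eV⁻¹, max 95%) map the panel's ω⁻ range ≈ 3–7 eV onto the
observed 0–90% DPPH range. The link is openly synthetic — the underlying
science claims only a qualitative, monotone association — so simulation-based
tests check rank recovery (Spearman ρ > 0.9 at 1 pp replicate noise), never
absolute percentages. Replicate absorbances are back-computed from the noisy
percentages so the percentage formulas invert the generator exactly at zero
noise. All generators take explicit integer seeds through
`numpy.random.default_rng`.

## Known data defects in the published panel

The shipped dataset reproduces the printed tables verbatim, including three
internal inconsistencies, and the acceptance tests assert the printed values
(failing deliberately rather than encoding a silent correction):

* gap cells of derivatives 2 and 4 differ by one unit in the last printed
  place from LUMO − HOMO of their own printed orbital energies (6.72 vs 6.73;
  6.31 vs 6.30) — consistent with independent rounding of full-precision
  values;
* derivative 3's printed LUMO (−1.93 eV) is irreconcilable with its printed
  gap (6.70 eV; the orbital pair implies 5.44, and a consistent LUMO would be
  −0.67) — a transcription error, which is also why the gap-ordering check
  ranks the printed gap column rather than recomputed gaps;
* the DPPH table's derivative-2 ratio against the parent drug (1.92) does not
  match its printed means (5.8/2.5 = 2.32), although the same row's ratio
  against BHT does — the single cell is erroneous.

## Problem sizes and numerical choices

The random-grid identity checks use 10⁴ (I, A) pairs; the synthetic round
trip 10³ compounds; the null calibration 10³ panels — sizes at which every
check is exact or statistically stable while the whole suite stays
desk-scale. Tolerances: 1e−9 eV for algebraic identities and round trips,
±0.02 for reproducing table cells derived from inputs printed at 2 dp (one
ulp of input rounding propagates to about that much in ω), printed precision
for ratio cells. Hypothesis-based property tests run derandomized.

## Limitations

No quantum-chemistry engine, no parsing of QC log files, no dose–response
(IC50) fitting — the assay model is single-concentration, as in the protocol
it mirrors. Region labels are geometric classifications, not pharmacological
claims; published significance stars cannot be reproduced exactly because the
underlying raw absorbances are not public, so the statistical layer is
validated by construction and calibration instead.
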
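# damkit

Conceptual-DFT reactivity descriptors, donor–acceptor maps, and antioxidant
assay statistics.

`damkit` is for medicinal and computational chemists who screen candidate
antioxidants — here, dapsone (DDS, 4,4′-diaminodiphenylsulfone) and its imine
derivatives — by combining electronic-structure descriptors with DPPH and
FRAP in vitro assay data. Quantum-chemistry energies are *inputs*: the package
starts where the electronic-structure code stops.

## The descriptors

From the total energies of a compound's neutral, cationic and anionic species
(vertical picture):

```
I = E(cation)  − E(neutral)        vertical ionization potential
A = E(neutral) − E(anion)          vertical electron affinity
```

and from these the electrodonating and electroaccepting powers

```
ω⁻ = (3I + A)² / (16 (I − A))      lower  ω⁻ → better electron donor
ω⁺ = (I + 3A)² / (16 (I − A))      higher ω⁺ → better electron acceptor
```

The donor–acceptor map (DAM) normalizes these against atomic anchors —
fluorine for acceptance, sodium for donation:

```
Ra = ω⁺ / ω⁺(F)        electron acceptation index
Rd = ω⁻ / ω⁻(Na)       electron donation index
```

The unit lines Ra = 1 and Rd = 1 partition the (Rd, Ra) plane; low Ra with
low Rd marks antioxidant (electron-donor) character, high Ra with high Rd
antireductant character. Frontier orbitals give the complementary
`gap = E(LUMO) − E(HOMO)` reactivity measure, and the assay module converts
replicate absorbances into DPPH %capture (`100·(A_c − A_s)/A_c`), FRAP
%reduction relative to an ascorbic-acid control, reference ratios, and
ANOVA + Dunnett many-to-one significance codes.

## Worked example

```python
import pandas as pd
from damkit import ReactivityDescriptors, DonorAcceptorMap

panel = pd.DataFrame(
    {"compound_id": ["DDS", "4", "BHT"],
     "i_pot":       [7.78,  8.63, 7.63],
     "e_aff":       [-1.10, 1.65, -1.64]}   # eV
)
X = ReactivityDescriptors(input_kind="direct").fit_transform(panel)
print(DonorAcceptorMap().fit().transform(X).round(4).to_string(index=False))
```

```
compound_id  i_pot  e_aff  omega_minus  omega_plus     ra     rd   region_label
        DDS   7.78  -1.10       3.4813      0.1413 0.0612 1.0139 donor-acceptor
          4   8.63   1.65       6.7913      1.6513 0.7154 1.9780 donor-acceptor
        BHT   7.63  -1.64       3.0445      0.0495 0.0215 0.8867    donor-donor
```

Dapsone's ω⁻ of 3.48 eV is the lowest of its derivative series (the 4-nitro
derivative "4" is the highest at 6.79 eV), so the parent drug is the series'
best electron donor, while the nitro derivative is its best acceptor
(Ra = 0.72 versus 0.06); the BHT standard sits in the donor–donor region,
donating even more readily than the sodium anchor (Rd = 0.89 < 1).

The same pipeline is scriptable from the shell:

```
damkit descriptors --direct panel.csv --out report.tsv
damkit dam --direct panel.csv --out dam.csv --plot dam.png
damkit rank --direct panel.csv --key omega_minus
damkit assay dpph --table absorbances.csv --parent DDS --standard BHT --out dpph.tsv
damkit simulate --spec sim.json --out-prefix scratch/sim
```

The full printed study panel (10 derivatives, DDS, BHT, ascorbic acid, F and
Na anchors, plus both assay tables) ships as `damkit.datasets` for use as a
worked dataset and regression anchor.

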
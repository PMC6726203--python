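# ircmech

Mechanistic analysis of enzymatic group-transfer reaction paths.

Protein kinases transfer the γ-phosphate of ATP to a serine or threonine
hydroxyl. Whether that transfer goes through a *tight* (associative,
phosphorane-like) or *loose* (dissociative, metaphosphate-like) transition
state — and whether the pathway is concerted or stepwise — is read off
quantum-chemical reaction-path data: geometries, energies, Wiberg bond
orders and NPA atomic charges computed along an intrinsic reaction
coordinate (IRC). `ircmech` implements that analysis layer for
computational chemists and structural enzymologists who already have the
path data (or want a synthetic stand-in) and need the mechanistic
descriptors:

* **Stationary-point topology** — reactant, transition states (TSs),
  intermediates and product located on the potential-energy profile, with
  relative energies; one interior maximum means a concerted pathway, two
  maxima flanking an interior minimum mean a stepwise one.
* **Pauling associativity** — at a TS with breaking and forming P–O
  distances d₁ and d₂, the fractional bond number *n* follows from
  Pauling's relation

  D(n) = D(1) − 0.60·log₁₀(n),  D(1) = 1.73 Å (single P–O bond),

  evaluated at D = (d₁+d₂)/2. 100·n is the percent associative character;
  n → 0 is a loose, metaphosphate-like TS.
* **Synchronicity** — bond-order derivatives dB/dξ along the reaction
  coordinate ξ: positive peaks mark bond formation, negative peaks bond
  breaking, peak offsets quantify how synchronous the events are, and
  curve crossings mark equal advancement of two processes.
* **Charge evolution** — per-atom NPA charges aggregated into named
  fragments (the transferred PO₃ group, the Mg²⁺ cofactor, catalytic side
  chains), tabulated at stationary points and correlated with bond events.

A synthetic-path generator with known ground truth (logistic bond-order
transitions, spline energy profiles, conserved charges, geometry coupled
to bond orders through the inverted Pauling relation) makes the whole
pipeline testable without any quantum chemistry.

## Worked example

The one-line calculation at the heart of the TS classification:

```python
>>> from ircmech import pauling_bond_number
>>> r = pauling_bond_number(3.04, 2.10)   # leaving / entering P-O, Angstrom
>>> print(f"Davg = {r.Davg} A, n = {r.n}, {r.pct_dissoc}% dissociative")
Davg = 2.57 A, n = 0.039, 96.1% dissociative
```

A TS with P–O distances of 3.04 and 2.10 Å retains only 3.9 % of a full
P–O bond on average — an emphatically loose, dissociative transition
state.

End to end, from the command line:

```sh
ircmech synthesize --preset base_assisted_like --outdir demo
ircmech analyze --config demo/config.yaml --out demo/report.json
```

The `base_assisted_like` preset emulates a stepwise, dissociative
phosphoryl transfer: barrier 14.3 kcal/mol, a shallow metaphosphate-like
intermediate 1.1 kcal/mol below the first TS, and two late proton
transfers slightly offset from each other. From `demo/report.json`:

```text
pathway:    stepwise
barrier:    14.38                       # kcal/mol, from the noisy profile
stationary: reactant 0.0 | TS1 8.2 | Int 7.1 | TS2 14.4 | product 2.6
pauling:    TS1 n=0.046 (95.4% dissociative), TS2 n=0.042 (95.8%)
events:     P-O3B breaking @ xi=0.20, P-OG forming @ 0.45,
            N-H breaking / O2G-H forming @ 0.70 (Lys -> phosphate),
            O-H breaking / OD1-H forming @ 0.75 (Ser -> Asp)
PO3 charge minimum: -1.03 a.u. near the intermediate
```

The PO₃ fragment dipping to ≈ −1 a.u. at the intermediate is the charge
signature of a metaphosphate species, independently confirming the
dissociative geometry.

Other subcommands (`mechanism`, `synchronicity`, `charges`, `geometry`)
run single stages on the same config; `--help` documents every threshold
default.

## Input formats

* multi-frame XYZ trajectory, optional `energy=<kcal/mol>` comment token
  (Hartree inputs: set `energies_in_hartree: true`, conversion ×627.5095);
* long-format CSV tables: bond orders (`frame,i,j,order`) and charges
  (`frame,atom_index,charge`);
* the NBO "Wiberg bond index matrix" text block
  (`ircmech.parse_wiberg_block`; frozen example under `tests/data/`);
* PDB for atom naming;
* one YAML config naming atoms, fragments and thresholds (see
  `ircmech.config` for the full key reference).
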
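# Methods

## Scope and model

`qcpost` post-processes electronic-structure outputs for a compound
series; it performs no electronic-structure computation itself. Four
analyses are implemented, each a standard model with explicit
assumptions:

**Global reactivity descriptors.** Koopmans-type frontier estimates
I = −E_HOMO, A = −E_LUMO for a gapped closed-shell ground state, then
χ = (I+A)/2, µ = −χ, η = (I−A)/2, S = 1/(2η), ω = µ²/(2η). Two
published-table conventions deserve note. First, descriptor tables
commonly print |µ| under "chemical potential"; we store the signed
(negative) µ and emit a magnitude field for table parity. Second, the
electrophilicity index is sometimes typeset "µ/2η"; the quantity
actually tabulated in our reference series is µ²/(2η)
(Parr–Szentpály–Liu), which is what we implement — every printed ω
column value matches µ²/(2η) and none matches µ/(2η). Softness "1/2η"
is likewise parsed as 1/(2η), confirmed by the printed values. A
degenerate input (E_HOMO = E_LUMO) raises an error rather than
returning infinite softness. Energies are hartree internally
(conversion factor 27.211386 eV/hartree at the presentation layer);
the descriptor table of the reference series is unit-annotated as
hartree because its magnitudes (~0.3 for I) are only consistent with
that unit.

**Condensed Fukui indices.** Charge-based finite differences over the
N−1/N/N+1 electron states: f−(k) = q_cat(k) − q_neu(k),
f+(k) = q_neu(k) − q_an(k), f0 their mean, dual descriptor f+ − f−.
With charges q = Z − p this differs from population-based definitions
only in sign bookkeeping; the chosen signs reproduce the nonnegative
dominant entries of the reference tables. Unit-charge closure
(Σf± = 1) is diagnosed at a configurable tolerance (default 1e-3, the
scale of last-digit rounding in printed charge tables) and recorded,
not raised. Negative condensed values — a known Mulliken-type
artifact — are kept and flagged, never clipped. The verbal mapping of
f−/f+ onto "nucleophilic"/"electrophilic attack" is contested in the
literature; ranking is convention-free over a column, and the default
labeling follows the reference series' usage (f− ↔ nucleophilic
attack) with a `standard` switch for the usual conceptual-DFT
assignment. Atom indexing is 1-based to match published tables.

**RRHO thermochemistry.** Ideal-gas translation (Sackur–Tetrode at the
stored pressure, default 1 atm = 101325 Pa), classical rigid rotor
(linear or asymmetric top, symmetry number σ), independent harmonic
modes (θ = hcν̃/k_B), and an R·ln g electronic degeneracy term.
H(T) = E_trans + E_rot + E_vib + RT relative to 0 K, with ZPE included
by default and the toggle recorded in output, since published plots
rarely state their enthalpy baseline; G = H − TS by definition.
Non-positive (imaginary) frequencies are dropped with a logged count.
No anharmonicity or hindered rotors; a Grimme/Head-Gordon QRRHO
low-frequency entropy interpolation (damping at 100 cm⁻¹) is available
behind a flag but off by default. The default grid is 10–500 K in
10 K steps, the range of the reference study. Numerics: Boltzmann
factors are evaluated with `expm1`/`log1p` forms and the vibrational
Cv uses the e^{−x} form to avoid overflow as T → 0 (x capped at 500,
beyond which thermal contributions underflow to zero anyway).
Constants are the SI-exact CODATA values via `scipy.constants`.

**Formula descriptors.** Hill-order formula parsing (case-sensitive
symbols, implicit count 1), average molar mass from IUPAC conventional
atomic weights (C 12.011, H 1.008, N 14.007, O 15.999, Cl 35.45, …),
monoisotopic mass from principal-isotope masses (¹²C = 12 exactly,
¹H 1.00782503, ¹⁴N 14.00307400, ¹⁶O 15.99491462, ³⁵Cl 34.96885268),
both tables versioned and the version echoed into every report.
Adduct masses subtract the electron mass (0.00054858 Da) for [M+H]⁺ by
mass-spectrometric convention, toggleable for parity with sources that
add a neutral hydrogen. Oxygen balance defaults to the classic
CHNO-to-CO₂/H₂O formula with halogens ignored,
OB% = 1600(nO − 2nC − nH/2)/MW; a `halogen-HX` variant replaces the
hydrogen term with (nH − nX)/2. The convention used is recorded in
the output. Report values are rounded half-to-even (2 decimals for
percentages, 4 for exact masses) with raw doubles retained internally.

## The fixture series

The built-in series reconstructs six bis-tetrazole acetamides
(6a–6f) from their published characterization data: formulas from the
elemental-analysis blocks, orbital energies as the negated printed
I/A columns, and charge triples inverted from published per-atom
f−/f+ rows (q_neu = 0, q_cat = f−, q_an = −f+), completed to full
molecules by spreading the residual 1 − Σf uniformly over unanchored
atoms so closure holds exactly and anchored rows are untouched. Only
rows confirmed unambiguously by the accompanying discussion are used
as anchors (compound 6d atoms 7–10 and 39–40; compound 6f atoms 10
and 31); rows whose digits are garbled in the published tables are
excluded. The published calcd masses of 6a/6b/6d match the neutral
monoisotopic sum despite their "+H" label and are asserted as such;
6c's printed value corresponds to a one-³⁷Cl isotopologue and is not
used as an anchor.

Frequencies and rotational constants for 6a–6f were never published;
the fixture generator synthesizes them (3N−6 log-uniform modes in
20–3500 cm⁻¹, seed 20230814). Thermochemistry on these fixtures is
therefore validated only through properties — closed-form
Sackur–Tetrode agreement, monotonicity of S and H, the G = H − TS
identity, equipartition and symmetry-number limits, mode additivity —
and a passing suite says nothing about the numerical S/H/G curves of
the real compounds. `random_record` produces seeded records with
exact unit-charge closure for property tests.

One reconstruction caveat: the published descriptor column of
compound 6a is internally inconsistent (its printed gap/µ/η/S/ω
derive from an I of ~0.31697, while the I column prints 0.3169).
Regression tests therefore compare at the printed-input rounding
bound, obtained by first-order propagation of half-widths 0.5·10⁻ᵈ of
the printed I/A digits into each descriptor; for five of the six
compounds this bound is dominated by the blanket 1e-4 tolerance.

A note on one oracle constant: the textbook translational entropy of
argon at 298.15 K, 154.85 J mol⁻¹ K⁻¹, is the 1 bar value; at 1 atm
the closed form gives 154.74 (the difference is R·ln 1.01325). Tests
anchor the 1 bar number and separately verify the implementation
against the closed form at 1 atm.

## Problem sizes and determinism

All computations are desk-scale: the full test suite (including 100
record round-trips per format and the 50-point thermal grids over
six ~60-atom fixtures) runs in a few seconds on one core, and
`scripts/acceptance.py` in well under a second. Everything is
deterministic given seeds: fixture synthesis uses a fixed seed,
property tests use seeded RNGs or derandomized hypothesis profiles,
and the pipeline records its settings and table versions in report
metadata so a run can be reproduced bit-identically.

## Known limitations

- Koopmans-type I/A ignore orbital relaxation; descriptors inherit
  that bias from the upstream calculation.
- Condensed Fukui indices depend strongly on the population-analysis
  scheme, which fixtures deliberately leave unspecified.
- The RRHO model breaks down for low-frequency torsions; the QRRHO
  flag mitigates but does not remove this.
- The formula layer handles composition only — no structures, no
  isotope-pattern simulation, no heat-of-formation or detonation
  performance estimates.
- The log-dialect parser targets this package's own writer (plus
  tolerated foreign lines); it is not a general quantum-chemistry log
  parser.
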
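# qcpost

Post-processing for the computational characterization of a small-molecule
series: given per-compound quantum-chemistry outputs (frontier orbital
energies, per-atom charges of the N−1/N/N+1 electron states, harmonic
frequencies, mass and rotational data), `qcpost` computes

- **global conceptual-DFT reactivity descriptors** — from Koopmans-type
  estimates I = −E_HOMO, A = −E_LUMO: electronegativity χ = (I+A)/2,
  chemical potential µ = −χ, hardness η = (I−A)/2, softness S = 1/(2η)
  and the electrophilicity index ω = µ²/(2η);
- **condensed Fukui indices** — finite differences of atomic charges,
  f−(k) = q_cat(k) − q_neu(k), f+(k) = q_neu(k) − q_an(k),
  f0 = (f−+f+)/2, the dual descriptor f+−f−, and site-reactivity
  rankings;
- **RRHO thermochemistry** — ideal-gas S(T), H(T), G(T) on a 10–500 K
  grid from Sackur–Tetrode translation, classical rigid-rotor rotation
  and harmonic vibrational partition functions;
- **formula descriptors** — average and monoisotopic ("HRMS calcd")
  masses, elemental-analysis percentages, nitrogen content and oxygen
  balance OB% = 1600·(nO − 2nC − nH/2)/MW, the energetic-material
  screening numbers.

It ships a fixture generator that reconstructs a published
bis-tetrazole acetamide series (compounds 6a–6f) from its printed
characterization tables, so the whole pipeline is testable without any
electronic-structure computation. The intended audience is
computational/medicinal chemists who want a reproducible, scriptable
version of the usual "post-DFT" analysis tables.

## Worked example

```python
>>> import qcpost as q
>>> g = q.global_descriptors(q.OrbitalEnergies(e_homo=-0.31875, e_lumo=-0.18960))
>>> round(g.hardness, 6), round(g.softness, 4), round(g.electrophilicity, 5)
(0.064575, 7.7429, 0.50023)
```

These are compound 6b's hardness (hartree), softness (hartree⁻¹) and
electrophilicity index (hartree): a moderately hard, weakly
electrophilic aromatic. Formula descriptors for the most
nitrogen-rich member of the series, 6d:

```python
>>> f = q.parse_formula("C24H16N14O10")
>>> round(q.monoisotopic_mass(f), 4), round(q.nitrogen_percent(f), 2), round(q.oxygen_balance(f), 1)
(660.1174, 29.69, -111.4)
```

660.1174 Da is the neutral exact mass quoted by HRMS; 29.69 % nitrogen
and an oxygen balance of −111.4 % (oxygen-deficient, but the least so
in the series) are the numbers that flag 6d as the energetic-material
candidate. The full report bundle:

```bash
qcpost report --builtin --out report/
qcpost descriptors fixtures/6b.json --round 6
qcpost fukui fixtures/6d.json --round 4     # atom 10: f0 = 0.4918
qcpost thermo fixtures/6f.json --tmin 10 --tmax 500 --step 10
```

`report/rankings.json` names 6e the softest / most electrophilic /
lowest-ionization member and 6d the highest-N%, smallest-|OB| member.

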
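# photoferro

Analysis toolkit for the electron-transfer chain of photoferrotrophic iron
oxidation — the process by which anoxygenic phototrophs such as
*Rhodopseudomonas palustris* TIE-1 use light to oxidize Fe(II), passing
electrons from an outer-membrane porin–cytochrome complex (PioAB) through a
periplasmic high-potential iron–sulfur protein (HiPIP, PioC) to the
light-harvesting reaction center (LH-RC, ~430 mV vs SHE).

The package implements, as a tested reusable pipeline, the computational
stages behind this kind of study, each exercisable end to end on seeded
synthetic data with planted ground truth:

| stage | module | what it computes |
| --- | --- | --- |
| NMR interface mapping | `photoferro.titration` | per-residue combined shift Δδ = √(ΔδH² + (α·ΔδN)²) and intensity ratios; classification shifted / broadened / doubled / missing; interface residue sets |
| redox-Bohr thermodynamics | `photoferro.redox` | E<sub>m</sub>(pH) = E<sub>alk</sub> + (RT ln10/F)·log₁₀[(1+10^(pK<sub>a,red</sub>−pH))/(1+10^(pK<sub>a,ox</sub>−pH))]; bounded least-squares fits with profile-likelihood bound flags; electrode conversion (+210 mV Ag/AgCl 3 M KCl → SHE) |
| hyperfine temperature dependence | `photoferro.tempdep` | OLS slopes of δ(T) for hyperfine-shifted signals; Curie / anti-Curie / flat classification; slope-set comparison between proteins |
| structure & sequence comparison | `photoferro.structure`, `photoferro.sequence` | Kabsch CA superposition (RMSD), fixed-column PDB I/O, global Needleman–Wunsch alignment (BLOSUM62, affine gaps), percent identity, conservation of interface sets, permutation test for residue clustering around the 4Fe-4S cluster |
| UV-vis redox quantification | `photoferro.spectra` | Soret peak localization (420 nm reduced → 409 nm oxidized), two-state spectral unmixing for the oxidized fraction, Beer–Lambert concentrations, ET feasibility ΔE(pH) scans |
| synthetic study conditions | `photoferro.synth` | seeded generators for every input above, with planted truth records |
| orchestration | `photoferro.pipeline`, `photoferro.cli` | config-driven interface-mapping and two-protein comparison reports (JSON, with input digests and thresholds) |

## Worked example

Fit the redox-Bohr model to a simulated E–pH campaign of a strongly
pH-dependent HiPIP (pK<sub>a,ox</sub> 5.5, pK<sub>a,red</sub> 8.2, 3 mV
scatter, pH 4–10):

```sh
python examples/02_redox_bohr_fit.py
```

```
generating: E_alk=380.0 mV, pKa_ox=5.5, pKa_red=8.2
fitted:     E_alk=378.7 mV, pKa_ox=5.49, pKa_red=8.22
bound flags: {'pka_ox': 'well_defined', 'pka_red': 'well_defined'}
Bohr amplitude: 161.0 mV (truth 159.7 mV)
```

The Bohr amplitude, (RT ln10/F)·(pK<sub>a,red</sub> − pK<sub>a,ox</sub>),
is the total pH-driven drop of the midpoint potential: ~160 mV for this
parameter set versus ~24 mV for a weakly coupled protein (pK<sub>a</sub>
pair 7.6/8.0). That difference decides whether the protein can still reduce
a ~430 mV acceptor at low pH (see `examples/05_spectral_unmixing.py` for
the feasibility scan).

The other `examples/*.py` scripts each demonstrate one capability —
interface mapping, temperature-dependence classification,
structure/sequence comparison, spectral unmixing, and the full
config-driven pipeline — printing the numbers they compute and one line on
what they mean. The same operations are available from the shell via the
`photoferro` command (`photoferro simulate|csp|redoxfit|tempdep|uvvis|etscan|run --help`).

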
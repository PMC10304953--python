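# Methods

This note records the models, parameter choices and numerical decisions
behind each analysis stage, and what the synthetic study conditions do and
do not establish about real data.

## Chemical-shift perturbation mapping

Binding of an unlabeled partner to a ¹⁵N-labeled protein is read out
residue by residue from a free/bound pair of assigned ¹H-¹⁵N peak lists.
Two observables are scored:

* combined shift change `d_comb = sqrt(dH^2 + (alpha*dN)^2)` with the
  Williamson weighting `alpha = 0.14` (0.20 for glycine). The weighting
  compresses the ~5x wider ¹⁵N dispersion onto the ¹H scale; any positive
  alpha rescaled together with dN leaves `d_comb` unchanged.
* intensity ratio `I_bound / I_free`, reporting exchange broadening. When
  linewidths are recorded an analogous rule on the ¹H linewidth increase
  can be selected instead; heights are the default because they are always
  available.

Classification is distribution-based: a residue is *shifted* when
`d_comb` exceeds the mean plus `k` standard deviations (k = 1) over all
matched residues, *broadened* when its intensity ratio falls below the
mean minus `k` standard deviations, *shifted+broadened* when both hold.
The statistics are computed over all matched residues without iterative
pruning — the simplest reproducible rule; with a minority of perturbed
residues the perturbed entries inflate the spread and the rule remains
conservative. A residue whose bound peak has vanished is classified
*missing* and counted as broadening beyond detection in the interface set
(exchange broadening past the detection limit is the usual cause in a
titration). Residues observed as two bound peaks are slow-exchange
conformational doubling; they are detected separately with resolution
tolerances (0.02 ppm ¹H, 0.1 ppm ¹⁵N) and reported with their
minor/major intensity ratio.

Thresholds need distributional support, so at least five matched residues
are required; with zero variance (free == bound) every residue is
unaffected and a warning is emitted.

## Redox-Bohr thermodynamics

For one electron coupled to one proton,

    E_m(pH) = E_alk + s * log10[(1 + 10^(pKa_red - pH)) / (1 + 10^(pKa_ox - pH))]

with `s = RT ln10 / F` computed from the temperature (59.16 mV at
298.15 K) rather than hard-coded, so simulations at other temperatures
stay consistent. The curve is monotone non-increasing for
`pKa_red >= pKa_ox` (reduction raises proton affinity) and its total drop
— the Bohr amplitude — is `s * (pKa_red - pKa_ox)`. The amplitude is the
pH→±∞ limit; over the finite pH 0–14 window it matches the numeric drop
to < 0.1 mV only while both pKas lie in the working range [3, 11], which
is also the default fit box.

Fitting uses bounded trust-region least squares in SHE space (all
potentials are converted first; Ag/AgCl 3 M KCl adds +210 mV).
Initialization is data-driven: alkaline limit from the two highest-pH
points, pKa pair centred on the half-drop pH with separation from the
observed span. If the unconstrained optimum violates the pKa ordering,
the fit is repeated with the separation parameterized as non-negative and
a warning is emitted. Confidence intervals are 95% Wald intervals from
the numerical Jacobian.

A pKa outside the measured pH window is confounded with `E_alk`, so the
data determine only a one-sided bound for it. Each pKa therefore carries
a flag: pinned within 0.05 of a box bound, or — the common case —
detected by profiling: the pKa is fixed at each box bound in turn, the
other parameters refitted, and if the residual sum of squares stays
within a chi-square(1, 0.95) threshold at the fit's noise scale all the
way to a bound, the estimate is flagged `lower_bound` (flat upward) or
`upper_bound` (flat downward).

Simulated campaign conditions: the recovery experiments use pH 4–10 in
0.2 steps with 3 mV Gaussian scatter (a dense, well-instrumented
campaign); `RedoxScenario.measured_window` emulates the experimentally
accessible window instead — 8 pH points across 6.0–8.1 with 8 mV scatter,
typical midpoint reproducibility of protein-film voltammetry. On the
dense grid all three parameters of both parameter sets (7.6/8.0 and
5.5/8.2) are recovered with mean pKa error < 0.1; on the measured window
the pKas lying outside it are usually flagged as one-sided bounds, which
is the behaviour the flags exist to report.

## Hyperfine-shift temperature dependence

The reduced 4Fe-4S cluster of a HiPIP is diamagnetic in its ground state
with thermally populated paramagnetic excited states; signals outside the
diamagnetic envelope (|δ| > 15 ppm by default, configurable) from
cluster-ligand cysteine β-CH₂ protons move with temperature. Each signal
is fitted with an ordinary least-squares line δ = a + b·T. Regression is
against T (the temperature dependence is reported and plotted against T;
a 1/T regression is provided as an option, with the sign logic inverted).
Classification: *anti-Curie* when the shift moves away from the
diamagnetic position as T rises (positive slope for downfield signals;
the convention inverts for upfield signals), *Curie* for the opposite,
*flat* within `flat_threshold = 0.005 ppm/K` of zero — roughly ten times
the OLS slope error on a 6-point series at 0.01 ppm measurement noise, so
a flat call is not noise-driven.

Two proteins' slope sets are compared by the ratio of mean slopes:
*similar* requires the ratio within `rel_tol = 0.25` of one and a single
shared classification; mixed classifications within either protein make
the comparison *not_comparable*. Equal slopes with different absolute
shifts indicate the same cluster electronic structure with different
cysteine coordination geometry; the module reports the numbers only.

## Structure and sequence comparison

PDB I/O is a fixed-column ATOM/HETATM reader/writer (3-decimal
coordinates; malformed fields are reported with their line number);
cluster atoms are HETATM records named SF4 or FES. Superposition is the
closed-form Kabsch algorithm (SVD with reflection correction), requiring
at least three non-collinear pairs; CA atoms only by default.

Global alignment is Needleman–Wunsch with affine gaps (gap of length L
costs `open + L*extend`; defaults 10 / 0.5 on the half-bit BLOSUM62
scale), executed via Biopython's PairwiseAligner behind this module's
interface. The optimal score is unique and is verified against an
exhaustive alignment enumerator on short sequences; the reported
traceback is the aligner's first optimal alignment (deterministic for a
fixed library version). Percent identity defaults to the aligned-pairs
denominator; the alignment-length convention is also exposed because
published identity values rarely state their denominator.

Whether an NMR-derived residue set clusters around the cluster cofactor
is tested by permutation: the statistic is the mean over the set of each
residue's minimum heavy-atom distance to any cluster atom (a proxy for
cofactor accessibility; no solvent-accessibility calculation is
attempted), the null draws uniform same-size residue subsets, and
p = (1 + #{null <= observed}) / (B + 1), deterministic given the seed.
Ties are compared with a 1e-9 tolerance so identical subsets encountered
in a different summation order count as ties.

## UV-vis redox state and ET feasibility

Spectra are treated as two-state linear mixtures of a reduced basis
(Soret at 420 nm, β/α bands at 520/550 nm) and an oxidized basis (Soret
at 409 nm, α/β bleached). The oxidized fraction has the closed form
`f = <s - r, o - r> / ||o - r||^2` clipped to [0, 1]; identical bases are
rejected as unidentifiable. No intermediate species are modelled — the
two-state assumption matches a single-transition oxidation series — and
NADP⁺ is treated as spectrally inert below 700 nm. Soret maxima are
refined by a parabola through the three points around the discrete
maximum, giving sub-grid accuracy on the 1-nm sampling; a maximum at a
window edge is returned unrefined.

ET feasibility against a fixed-potential acceptor (default 430 mV vs
SHE, the reaction-center potential scale of anoxygenic phototrophs) is
the sign of ΔE(pH) = E_acceptor − E_donor(pH); because the redox-Bohr
donor potential falls with pH, ΔE rises and a unique crossing, when
present, is located by root bisection.

## Synthetic study conditions

All generators flow from one integer seed, split into per-generator
streams by a stable key, so identical seeds reproduce identical outputs
and zero-noise outputs satisfy the generating model exactly. Noise is
Gaussian and independent per observation — the simplest model consistent
with instrument-level scatter and sufficient for recovery-style tests.

* Titration pairs: free-state peaks drawn once in the amide region
  (¹H 6.5–10 ppm, ¹⁵N 105–130 ppm); planted shifts default to
  0.06/0.35 ppm (¹H/¹⁵N), attenuation 0.4, effects applied to the bound
  list with noise added to the bound list only (the free list is the
  reference acquisition). The default residue set is a synthetic
  54-residue HiPIP-like sequence carrying the experimentally named
  residue types at the named positions; it is not any real protein's
  sequence. The truth record flags `recovery_uncertain` when a planted
  combined shift is below three times the combined noise floor.
* Toy structures: CA/CB trace on a gentle helix (radius 8 Å,
  25.2°/residue, 1.5 Å rise, CA–CA ≈ 3.8 Å — realistic inter-residue
  distances without modelling a real fold) with a 4-atom SF4 heterogroup
  placed 3.5 Å radially outward of the planted patch centroid, which
  guarantees a contiguous-ish patch is nearest the cluster; widely
  scattered patches are not guaranteed.
* Spectra: Gaussian bands at the stated centres on a 250–700 nm, 1-nm
  grid.

What passing on these conditions shows — and does not: recovery is
demonstrated under independent Gaussian noise, complete assignments, and
planted effect sizes typical of reported titrations. Real spectra carry
correlated baselines, peak overlap, incomplete assignments and
exchange-regime ambiguity that the generators deliberately omit, so
perfect recovery here validates the algorithms and thresholds, not the
difficulty of any particular experimental dataset.

## Problem sizes

Monte-Carlo experiments use 50 campaigns per redox parameter set, 100
seeds for slope similarity and unmixing recovery, 200 simulated datasets
for the pKa bias/RMSE property, B = 999–1999 permutations for patch
tests, and 50 seeded pairs (length ≤ 8) against the exhaustive alignment
enumerator — sizes at which the binomial/Monte-Carlo error of each check
is comfortably below its decision margin.

## Known limitations

* The CSP thresholds (k = 1 SD) reproduce set recovery on planted
  fixtures; published residue lists rarely state cutoffs, so threshold
  choices cannot be validated against literature values beyond recovery.
* The redox-Bohr model is single-proton (n = 1); multi-proton coupling
  and scan-rate effects are out of scope, as is raw voltammogram
  processing (midpoints enter as peak-potential pairs via `cv_midpoint`).
* The permutation patch statistic uses nearest-atom distance, not
  solvent-accessible surface; the two can disagree for buried residues.
* Exchange-regime kinetics (fast/slow classification from lineshape) and
  Kd estimation from titration curves are not modelled; ligand ratios
  are metadata only.
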
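# Methods

This note documents the models implemented in `hdxpipe`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Exchange model and units

All kinetics assume the EX2 limit: the observed exchange rate of residue
*i* is `k_int,i / PF_i`, where `k_int` is the intrinsic (unstructured-
chain) rate and `PF ≥ 1` the protection factor. Residue indices are
1-based inclusive everywhere; exposures are stored in seconds (DynamX
minutes are converted on read); `k_int` is reported in min⁻¹ and converted
at use sites. Uptake is stored back-exchange-uncorrected on read, and a
provenance flag on every table records whether the correction stage has
been applied.

## Intrinsic rates (`hdxpipe.rates`)

Rates follow the Bai–Englander poly-DL-alanine reference parameterization
for exchange in D₂O: acid, base and water branches with per-residue
inductive factors for a residue's own side chain (λ) and its predecessor's
(ρ), N-terminal ammonium and C-terminal carboxylate corrections, and
branch-wise Arrhenius scaling from 293 K with activation energies of
14 / 17 / 19 kcal/mol. The water branch uses the base-catalysis factors,
as in the original chemistry. The factor table ships as a versioned CSV
(`data/englander_factors.csv`). Choices a user may care about:

- `pD = pH_read + 0.4` (glass-electrode correction), disengageable.
- Asp/Glu are treated as carboxylates, His as neutral, Cys as reduced,
  prolines as trans — the reference states appropriate near pD 7–9. No
  per-residue pKa model: below ~pD 5 the ionizable-residue factors become
  inaccurate.
- `pK_D = 15.05`, held temperature-independent; over the 278–308 K range
  relevant here the error this introduces is small against the ~1.4×/5 K
  Arrhenius factor itself.
- Residue 1 (free amine) and prolines (no amide H) are non-exchanging and
  carry NaN.

A qualitative anchor: for an Ala context the rate-vs-pD curve is V-shaped
with its minimum near pD 3; at pD 8.3 and 298 K typical rates are
10²–10⁴ min⁻¹.

## Back-exchange correction (`hdxpipe.peptides`)

The correction uses a template peptide assumed fully exchanged at plateau:
`be = 1 − D_template(plateau) / N_exch(template)`, and every uptake and SD
is divided by `1 − be`. The plateau defaults to the largest timepoint —
on a 0.5/1/2-min schedule a fitted plateau is unstable for fast templates —
with a fitted-plateau option. A template whose uptake exceeds its
theoretical maximum is an error (it cannot be fully exchanged); a template
exactly at the maximum is a no-op.

`N_exch` counts exchangeable amides with the peptide's first residue and
all prolines excluded (`skip_first`, the DynamX-style convention; a
`skip_first_two` option exists because the first two residues' deuterons
are sometimes assumed lost during analysis). The same convention is used
consistently by the simulator, the maximum-uptake bound of the fitter and
the peptide aggregation of predictions, which is what makes experimental
and predicted uptake directly comparable.

## Overlapping-peptide subtraction

Only nested pairs sharing exactly one endpoint are subtracted (shared
start: overhang is the long peptide's extra C-terminal run; shared end:
the extra N-terminal run). SDs propagate in quadrature and a difference is
accepted when `|ΔD| > 5σ` (the multiplier is configurable). The rule is
applied per timepoint; a fitted-maximum mode can be composed manually by
subtracting fit plateaus. The overhang's own uptake does not re-apply the
first-residue exclusion: the subtraction already removes the shared
prefix's contribution. No multi-peptide least-squares deconvolution is
attempted — only pairwise subtraction.

## Exponential fitting and significance calls (`hdxpipe.kinetics`)

`D(t) = A(1 − e^(−kt))` is fit by weighted least squares (weights 1/σ²
where replicate SDs are nonzero, unit otherwise), bounds
`A ∈ [0, 1.2·N_exch]`, `k ∈ (0, 10] s⁻¹`, initialized at the maximum
observed uptake and `1/median(t>0)`. The t = 0 point is included and
anchors the baseline. On a four-point schedule `(A, k)` are weakly
identified for slow exchangers: when `k·t_max < 0.2` the result is flagged
`plateau_not_reached` and `A` is best read as a lower bound.
Non-convergent fits fall back to the last-timepoint uptake with an
unreliable (infinite) covariance; downstream differential calls mark such
peptides `unclassifiable` rather than guessing.

Differences `ΔD = A_bound − A_free` are classified with a dual threshold:
both `|ΔD| ≥ min_delta` (default 0.5 Da, below which instrument-scale
effects are not interpreted) and `|ΔD| ≥ m·σ_ΔD` (default m = 2) must
hold. Defaults are deliberately conservative for a three-replicate
experiment and are echoed into every output; no multiple-testing
correction is applied by default (a Benjamini–Hochberg step can be layered
on the exported calls table, but the per-peptide dual threshold is the
primary control, and on null simulations it yields ~2% significant calls,
well under the 7% design bound).

## MD hydrogen bonds and logistic protection (`hdxpipe.hbonds`)

An amide donor is H-bonded to an acceptor when the N···acceptor
heavy-atom distance is ≤ 3.5 Å and the H–N···acceptor angle is ≤ 30° —
common MD practice; both are config keys. Protein acceptors are protein
oxygens plus side-chain nitrogens; water acceptors are water oxygens
(water is counted as acceptor of the amide H only). The closed-state
observable defaults to "protein-bonded AND NOT water-bonded"; a
`protein_only` mode is kept for sensitivity analysis. Trajectories are
read through MDAnalysis (PDB/DCD/XTC); a per-frame flag CSV decouples the
rest of the pipeline from trajectory formats. Amide hydrogens must be
present in the topology; residues lacking them are reported by name
rather than silently skipped.

The closed fraction x maps to `ln PF = L / (1 + e^(−s(x−x0)))`, a
logistic in x with ceiling L, midpoint x0 and steepness s. PF is floored
at 1 (no catalysis below the intrinsic rate — the floor only matters for
pathological parameter sets since the logistic itself is positive).
Because published uses of this family fix their constants in supplementary
material, the package ships the parameterized family plus
`calibrate_logistic`, which fits (L, x0, s) to experimental maximum uptake
over the peptide map by SSE, seeding a Nelder–Mead refinement from a
deterministic coarse grid (bounds `L ∈ [0, ln 10⁹]`, `x0 ∈ [0,1]`,
`s ∈ (0,100]`). L and x0 are well recovered (≲ a few % on synthetic data
with ≥ 10 peptides); s is only weakly identified when closed fractions
cluster away from the midpoint — the SSE surface is profiled and a flat
surface triggers a warning. Fewer than ~100 frames makes closed fractions
noisy and warns.

## SASA and correlations (`hdxpipe.sasa`)

Shrake–Rupley sphere-point sampling with Bondi radii (versioned CSV) and
a 1.4 Å probe. The lattice is a deterministic Fibonacci sphere (default
960 points); each atom's lattice gets a deterministic orientation derived
from a fixed internal seed and the atom order, which decorrelates
discretization error between atoms so structure totals converge faster
than with a single shared orientation. Isolated-atom areas are exact to
≲0.1% at the default; the rotational variation of a structure total is
~0.1–0.2% at 960 points and ≤0.1% at the 15 360-point lattice used by the
rotation-stability checks. These few-per-mil discretization effects are
immaterial to uptake–SASA r² comparisons. Per-peptide backbone SASA sums
N, CA, C, O and the amide H when present (exchange happens at H; config
to drop). Missing residues are flagged, never modeled. Correlations are
ordinary least squares with Pearson r² on included points; outlier
candidates (|internally studentized residual| > 2.5) are surfaced sorted
by magnitude but never auto-removed — exclusion stays an explicit,
recorded decision.

## Synthetic data (`hdxpipe.synth`)

The generator emulates the study design the package targets: two states
differing by planted Δlog₁₀PF inside specified regions, labeling at 25 °C
in a pD 8.3 buffer (read pH 7.9 + 0.4), timepoints 0/30/60/120 s, three
replicates with Gaussian noise, a global back-exchange loss, and an
overlapping pepsin-like peptide map guaranteed to contain at least one
nested shared-start pair. The free-state landscape is `base_log10_pf = 3`
with ±1 uniform per-residue jitter, which places observed rates across
the 0.5–2 min window — fast enough to measure, slow enough that a 10-fold
PF change moves the 2-min plateau. `exposed_regions` force PF = 1 in both
states, providing the fully exchanged reference peptide the back-exchange
stage needs. Sequences are uniform over the 19 non-proline residues with
4% prolines. t = 0 rows are the nondeuterated reference (exactly 0 after
control subtraction); replicate noise applies at t > 0 and means are
clipped at 0.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: EX1/bimodal exchange, correlated replicate
error, chromatographic carry-over, peptide-dependent back-exchange,
isotope envelopes/charge states, and sequence-dependent pepsin cleavage
preferences. It validates the pipeline's arithmetic and statistics, not
instrument behavior.

All randomness sits behind integer seeds; generators are pure functions
of their seed.

## Problem sizes in the checks

The test suite and `scripts/acceptance.py` use 30–60-residue synthetic
proteins (7–12 peptides), 1000-seed Monte-Carlo for fit coverage,
100 random maps for the overlap oracle, 40 000-frame Bernoulli series for
calibration, and 500 null experiments for the false-positive rate —
sizes at which the measured quantities are stable to well within their
stated tolerances while the whole acceptance run completes in about a
minute.

## Known limitations

- Single-exponential fitting compresses genuinely multi-exponential
  peptide kinetics into an effective (A, k); A is then the 2-min-window
  plateau, not the thermodynamic maximum, exactly as in the experimental
  practice it mirrors.
- The intrinsic-rate module covers H→D exchange in D₂O at low salt only;
  no D→H (back-exchange direction) rates, no high-salt corrections.
- The logistic PF model is the only MD→PF route implemented; contact- or
  burial-count models are out of scope.
- H-bond criteria are geometric only; no energetic or occupancy smoothing
  beyond the frame average.
- PDB structures with missing residues yield flagged, not imputed,
  peptide SASA values.
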
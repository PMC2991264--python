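# Methods

`plaquedyn` quantifies the motion of chromosomal attachment plaques —
SUN/KASH-anchored chromosome-end attachment sites imaged as fluorescent
aggregates (e.g. SUN-1::GFP) on the nuclear envelope during
leptotene/zygotene. This note documents the models, the numerical
choices, and what the synthetic generator does and does not emulate.

## Observation geometry and kinematic statistics

Recordings are maximum-intensity projections sampled every 5 s for
15 min (181 frames). All kinematics operate on projected (image-plane)
positions in µm.

**Projected speed.** The per-step speed is the Euclidean 2D displacement
between successive samples divided by the frame interval, in nm/s.
Speeds are summarized into three bands: a *background* band [0, 40] nm/s
(the apparent motion measured in azide-immobilized specimens, i.e. pure
localization error), a *bulk* band (40, 160], and a *long tail*
(160, ∞). The band boundaries are closed on the right ([0,40], (40,160],
(160,∞)) because the verbal ranges they come from are ambiguous at the
edges; a distribution is flagged "long-tailed" when at least 5% of steps
exceed 160 nm/s — a threshold chosen so that wild-type-like motion
(≈10% of steps above 160 nm/s) is long-tailed while a restrained mutant
with 95% of steps within 10–100 nm/s is not.

**Arc travel statistic.** Total path length misrepresents confined
motion (small oscillations accumulate large path lengths without going
anywhere), so travel extent is measured as the angle β subtended on the
projected-nucleus circle by the chord between the track's two most
separated points. The extreme pair is found by exact O(n²) search
(tracks are short). With chord `c = √(a² + b²)` (a, b the axis-aligned
distances) and nucleus radius `r`, the cosine law gives
`β = arccos(1 − c²/2r²)`, equivalent to inverting `c = 2r·sin(β/2)`.
Handling of long chords is deliberately explicit, because the two
plotting conventions in circulation conflict (flagging chords beyond the
radius as "extended" vs. enlarging the circle): β is always computed on
the nominal circle while `c ≤ 2r`; a `dashed` flag records `c > r`
(the extended-arc plotting convention); only a chord longer than the
diameter — geometrically impossible to circumscribe — enlarges the
radius to the minimal circumscribing value `c/2` with β = 180°. Both the
flag and the effective radius are reported so either convention can be
tabulated. The nucleus circle is estimated from all aggregate centroids
as the minimal enclosing circle (Welzl's algorithm; least-squares Kåsa
fit optional), floored at 1 µm; since no canonical nucleus radius
exists, the radius used is carried in every arc result.

**3D reconstruction.** Assuming motion on one hemisphere of a sphere of
radius r centered on the nucleus, `z = √(r² − x² − y²)`. Localization
noise can push a sample outside the disk (`x² + y² > r²`); the previous
z-coordinate is then carried forward, and z = 0 is used if the *first*
sample is already outside (the carry-forward rule is undefined there).

## Segmentation

Each frame is high-pass filtered (small Gaussian smoothing minus a
large-Gaussian background estimate; this generic background-subtraction
stage replaces deconvolution, which needs the optical PSF). Background
estimation is two-pass: bright pixels found by a first pass are replaced
with the background median before the background is re-estimated, so
foreground flux does not bleed into (and flatten) the estimate.

The default automatic threshold is a **robust noise floor**: median +
k·σ (k = 5), with σ estimated from the *negative* side of the signed
residual (spots only add positive signal, so the lower half-distribution
stays uncontaminated even when foreground covers a third of the field).
A between-class (Otsu) threshold is available but is not the default:
aggregate brightness scales with the number of clustered chromosome
ends, so the foreground intensity distribution is multimodal and Otsu
settles between dim foci and bright patches, discarding the foci
(measured recall ≈ 0.7 vs ≈ 1.0 for the noise floor on rendered
fixtures). Both automatic options are invariant under multiplicative
intensity rescaling; a fixed threshold can be supplied for
reproducibility.

Touching aggregates are separated by a watershed on the distance
transform of the binary mask, seeded at distance-transform peaks at
least 0.3 µm apart. Regions below 0.1 µm² are discarded as hot pixels.
Region area is pixel count × pixel size²; aggregates with area
< 2.15 µm² are classified *foci*, ≥ 2.15 µm² *patches* (the published
strict inequalities leave the boundary undefined; it is assigned to
patch). Coordinates are µm from the image top-left corner, frames
0-based, time = frame × frame interval.

Objects closer than roughly the sum of their radii merge optically and
cannot be separated by any segmentation; for patch-sized objects
(≥ 0.8 µm radius) this happens at µm-scale separations. This is a
physical property of the data, not an implementation limit — it is why
fusion/splitting is counted from the aggregate-number time series rather
than from pixel overlap.

## Tracking

Detections are linked frame-to-frame by **optimal (minimum-total-
displacement) assignment** (Hungarian algorithm) restricted to a gate of
1.5 µm per 5 s frame (≈300 nm/s, just above the fastest observed
aggregate speeds of ~260 nm/s). A greedy nearest-neighbor linker was
evaluated first and agreed with exhaustive minimum-total-distance
matching only ~93% of the time on crossing trajectories; the optimal
assignment agrees ≥ 99.9% by construction, so it is the default.
Distance ties are broken by smaller area difference; new-track creation
follows a canonical (position-sorted) order, making linking invariant to
detection order within a frame.

Lineage follows the manual-tracking conventions of this assay: when two
tracks converge on one detection, the event is a *fusion* and the
identity of the larger-area track continues; when one track splits into
two detections, the *larger fragment keeps the identity* and the smaller
starts a new (child) track. Gap closing is off by default (tracking is
continuous at 5 s sampling).

Summary-table semantics: per-nucleus mean/min/max of the per-frame
aggregate count, then mean ± sample SD (n−1) across nuclei with n
reported.

## Events and coalescence times

Fusions and splittings are counted either directly from the merge/split
log (preferred) or from the count series N(t): a decrement of k counts k
fusions, an increment k splittings; the two agree exactly when no two
events share a frame (a same-frame fusion + splitting cancels in N(t)).
The analysis window defaults to the first 15 min.

The *coalescence time* of a fusion is the dwell until the merged
identity next participates in a splitting. Dwells truncated by the end
of the recording are flagged censored and excluded from binning by
default (inclusion is a flag). Dwells are binned half-open at
[0, 60), [60, 180), [180, ∞) s; per-nucleus event totals are binned
0, 1–5, 6–10, 11–15, 16–20, 21–25, with totals above 25 in a warned
overflow bin. When the merged aggregate fuses again before splitting,
identity hand-offs make lineage pairing ambiguous; measured dwell-class
shares are therefore slightly flatter than the generator's exponential
law (more mass in the ≥1 min classes), an effect any identity-based
pairing — including manual tracking — shares.

## Statistics

- **Mann–Whitney U**, two-sided; exact enumeration when n₁+n₂ ≤ 12
  without ties, tie-corrected normal approximation otherwise. The
  default unit of analysis is the pooled per-step speed; a
  per-nucleus-median mode is provided because pooling treats steps, not
  nuclei, as replicates.
- **Fisher's exact**, two-sided as the sum of probabilities of tables no
  more probable than the observed (the most common convention). 2×2
  solved exactly; 2×K by full enumeration of the margin-conditional null
  when N ≤ 30, otherwise Monte Carlo from the multivariate
  hypergeometric with a fixed seed (flagged non-exact).
- **ECDF difference** ECDF_foci − ECDF_patches on a speed grid: positive
  values mean foci are slower at that speed.
- **Size–speed correlation**: Pearson r per morphology class; constant
  input raises (undefined correlation).
- No multiple-testing correction by default (raw p-values are reported);
  Bonferroni/Benjamini–Hochberg can be applied downstream.

## Synthetic generator

The generator produces ground-truth trajectories so every stage is
testable without microscopy data. Defaults encode the standard study
conditions; all are configurable.

**Geometry and motion.** Aggregates live on the upper side of a sphere
of radius 2 µm (nucleus radii are not published; imaging scale bars are
2 µm), confined to a spherical cap about the +z pole (default 90°, one
hemisphere) with a radially reflecting boundary. Each frame the
aggregate takes an isotropic step in the *projected* plane, lifted back
to the sphere via `z = √(r² − x² − y²)`. Defining the step law in
projection is deliberate: an isotropic 2D Gaussian walk yields a
Rayleigh ("Maxwellian-shaped") projected-speed law, and the published
speed bands are defined on projected speeds, so the mixture below is
then exactly the distribution the analysis observes (a first
implementation drew the mixture as on-sphere arc speeds; projection then
compressed the observed bands by ~20%, inflating the background band
from ~24% to ~39%).

**Step-speed mixture.** With probability 1 − `tail_fraction` the speed
is Rayleigh with scale `speed_scale_nm_s`; otherwise uniform on
`tail_range_nm_s`. Wild-type defaults (σ = 51 nm/s, tail 0.10 on
(160, 260]) are solved from the published band shares: Rayleigh(51)
gives P(≤40) ≈ 0.265 and P(>160) ≈ 0.007, so the mixture lands at
≈ 24/66/10% background/bulk/tail. The restrained-mutant preset uses
σ = 41 (95% of a Rayleigh below 100 nm/s), no tail, no fusion; the
azide preset has zero true motion.

**Counts.** The initial per-nucleus count is a stochastic rounding of
`mean_aggregate_count` (3.9 by default). A Poisson option exists for
modeling across-nucleus heterogeneity, but the default keeps the initial
draw tight so recovered summary means reflect the kinetics; the
across-nucleus SD of ~1.4 seen in real summary tables is biological
heterogeneity the default deliberately does not inject. A fraction
(0.2) of initial aggregates start as two clustered ends (patches).

**Fusion/splitting.** Two aggregates within 0.45 µm (3D chord) fuse with
probability 0.15 per contact frame — values chosen so that simulated
nuclei fall mostly in the 1–5 and 6–10 events-per-15-min classes, the
most populated classes in real recordings. Each fusion pushes the
absorbed partner's constituent count onto the survivor's LIFO merge
stack and schedules one splitting after an exponential dwell
(mean 40 s, consistent with ~70–80% of coalescences lasting < 1 min; a
mean-matched lognormal is available since only binned dwell classes are
published). Each splitting pops one level: the larger fragment keeps the
identity, the smaller starts a child just outside fusion range. This
stack makes fusion and splitting exactly balanced, so the live count is
stationary: it equals the initial count plus cumulative
(splits − fusions) at every frame, and fluctuates only downward from the
initial value by the number of currently-merged pairs (mean deficit
≈ 0.1–0.2 under defaults).

**Observation model.** Projection drops z; isotropic Gaussian
localization noise (SD 20 nm, consistent with a [0, 40] nm/s apparent
background band at 5 s sampling: the per-step noise displacement is
Rayleigh with scale √2·20 nm ⇒ speed scale ≈ 5.7 nm/s, putting
essentially all mass below 40 nm/s) is added to x and y.

**Rendering.** Aggregates are drawn as 2D Gaussian spots on a 0.1 µm/px
grid (pixel size unpublished): footprint SD 0.26·√c µm and amplitude
150·c counts for c constituents, over a constant background of 10 counts
with Poisson shot noise. This calibration makes segmented areas ≈1.6 µm²
for c = 1 (focus) and ≥2.5 µm² for c ≥ 2 (patch) under the default
threshold, so constituent classes map onto the 2.15 µm² rule with
margin. The spot SD intentionally exceeds the diffraction limit —
attachment plaques are extended structures, not point emitters.

**What the generator does not emulate.** Photobleaching, drift, uneven
illumination, 3D PSF structure, and the chromatin channel are absent;
across-nucleus count heterogeneity is off by default (above); because
every fusion is eventually undone, the per-nucleus count never *exceeds*
its initial value, so the generator under-disperses the per-nucleus
maximum relative to real recordings (where new aggregates also form de
novo); and aggregates never appear or disappear at the recording
boundary mid-movie. Passing tests therefore demonstrate correctness of
the measurement pipeline on data whose geometry, kinetics and noise are
controlled — not robustness to every artifact of live imaging.

## Problem sizes and determinism

Every stochastic component takes an explicit seed (simulation, noise,
rendering, Monte-Carlo Fisher), and re-running any stage with the same
configuration is bit-identical; output CSVs carry a provenance header
(package version, config hash, seed). The test-suite and acceptance
computations use cohorts of 25–60 simulated nuclei and movies of tens of
frames, sizes at which every statistical check has comfortable margin
over its tolerance while the whole suite runs in well under a minute.
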
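# Methods

## Scope and model

The package analyzes multichannel task EEG as a band-specific
functional network: nodes are channels, edge weights are normalized
mutual information (nMI), and group inference is carried out on binary
graphs derived from the weighted matrix. It assumes the input
recordings are already artifact-cleaned (ocular/muscle component
removal is out of scope); preprocessing starts from a cleaned
continuous record.

## Preprocessing

Order of operations: 0.5–30 Hz zero-phase bandpass on the continuous
record → non-overlapping 10-s epochs (trailing remainder discarded) →
common-average reference per epoch → per-band zero-phase bandpass
applied epoch-wise. Filters are 4th-order Butterworth run
forward-backward (`sosfiltfilt`), so the effective magnitude response
is the square of the one-pass response and the phase response is zero.
Per-band filtering of short epochs uses 1 s of reflective padding at
each end to limit transients. Band edges are delta 0.5–3, theta 4–7,
alpha 8–13, beta 13–30 Hz; the 3–4 Hz gap and the shared 13 Hz edge
are kept as conventional.

Average referencing is linear and per-sample, so it commutes with the
band filters; epochs therefore remain zero-mean across channels after
band filtering (checked to 1e-6 of signal scale in the tests).

## Mutual-information connectivity

For two signals in one 10-s epoch, each is binned into 100 equal-width
bins spanning its own [min, max] within that epoch (a constant signal
occupies one bin and has zero entropy). MI is computed in bits from the
joint histogram as H(X) + H(Y) − H(X,Y), which is algebraically the
Kullback–Leibler form with 0·log 0 = 0 and is numerically clamped at 0.
Normalized MI divides by H(X) + H(Y), giving values in [0, 0.5]
mathematically (MI ≤ min H); the convention for two constant signals is
0. The subject-level matrix is the arithmetic mean of the per-epoch
matrices; its diagonal is fixed at 0 so self-connections never enter
graph construction.

**Estimator bias.** The 100-bin histogram estimator is positively
biased for finite samples; at 2500 samples per epoch (10 s at 250 Hz)
the bias floor for independent Gaussian pairs is ≈0.10 in nMI units and
shrinks with sample count. Absolute nMI values therefore mean little;
the analysis depends only on the ranking of pairs within a subject and
on comparisons across subjects computed identically. Where an absolute
MI value is needed (the bivariate-Gaussian closed-form check in the
validation suite), the bias is estimated by shuffling one signal and
subtracted.

## Network filtering

*Absolute threshold*: edge iff nMI strictly exceeds T; the default
sweep covers T ∈ (0.15, 0.45) in steps of 0.005 (59 points, endpoints
open). Graph density then differs across subjects.

*Mean degree*: the round(K·n/2) strongest edges, K ∈ (2, 8) step 0.1,
equating density across subjects; ties at the cutoff are broken by
ascending (i, j) order so results are platform-independent.

*OMST*: minimum spanning trees are extracted iteratively on the
distance d = 1 − nMI, each tree edge-disjoint from its predecessors;
after adding the m-th tree the objective
J(m) = E_glob(union) − Cost(union) is evaluated, where E_glob is the
weighted global efficiency (mean of 1/shortest-path-distance under d)
and Cost is the selected fraction of total connection weight. The union
maximizing J is returned, binarized. The choice d = 1 − w (rather than
1/w) keeps distances bounded as w → 0. Extraction stops when the
residual graph disconnects or after n−1 trees.

## Graph metrics

C is the mean over all nodes of 2·triangles/(deg·(deg−1)), with
degree < 2 nodes contributing 0 (computed from the adjacency cube). L
is the mean hop count over **connected pairs only**: disconnected pairs
are excluded from numerator and denominator. This convention is the
load-bearing choice for the absolute-threshold sweep — as T rises and
the graph fragments, L falls because only short within-component paths
remain. Alternatives (harmonic mean, largest component only) change
that signature. L is undefined (an error) for graphs with no connected
pair; the pipeline records such sweep points with C only.

## Null models and the small-world index

Each experimental graph is randomized by attempted double-edge swaps
((a,b),(c,d) → (a,d),(c,b)), rejecting self-loops and duplicates; the
chain length is 10·|E| attempts, a standard mixing heuristic. Degrees
are preserved exactly, so γ = C/⟨C_rand⟩ and λ = L/⟨L_rand⟩ compare the
graph against its own degree sequence. σ = γ/λ is computed per subject
on the OMST-filtered graph against 300 nulls (default); nulls with
undefined L would be regenerated (up to 10×), though with the
connected-pairs convention this effectively never occurs. On complete
graphs no swap is valid, so σ = 1 exactly — a fixed-point sanity check.

## Statistics

Group comparisons of C and L use the Mann–Whitney U test at every grid
point, reported SPSS-style: U = min(U₁, U₂) with midranks for ties, the
companion Wilcoxon W (rank-sum of the group attaining the minimum,
W = U + n_min(n_min+1)/2), and a two-sided p from the normal
approximation with tie-corrected variance and **no continuity
correction**. An exact-enumeration p is available for small samples.
The two agree to ≈0.001 in the significant tail (exact p < 0.02) at
n = 14 + 14 but diverge by up to ~0.026 at mid-range p, so the
asymptotic convention matters for reproducing published 3-decimal
values. No correction for multiple testing is applied across grid
points (the output metadata flags this); behavior uses pooled-variance
t-tests, correlations use Pearson r with a t-distribution p on n−2
degrees of freedom, and Shapiro–Wilk annotates normality without
gating anything.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
with known ground truth. Channels are partitioned into 4 scalp regions
(source clusters). Per band, each region has one band-limited Gaussian
source (white noise bandpassed to the band); a cluster-level coupling
graph states which regions share sources. A channel in region α mixes
the unit-variance sum of the sources in α's closed neighborhood at
coupling strength c with a private source: √c·shared + √(1−c)·private.
Channels also receive independent 1/f background noise
(`noise_scale` = 0.3 of unit band variance), and each channel is
standardized before scaling to microvolts, since histogram MI is only
approximately invariant to channel-wise scaling under binning.

Defaults (the study conditions asserted by the tests): 14 subjects per
group, 24 channels in a 10-20 montage, 250 Hz, 60 s per subject. The
control theta configuration couples the four regions through a frontal
hub (star adjacency) at strength 0.95 — an integrated network with
short paths. The patient-like configuration removes all inter-region
theta coupling and reduces the strength to 0.50 (a 47% reduction) — a
fragmented network whose binary graphs acquire longer characteristic
paths. All other bands use the star configuration at 0.85 in both
groups, so group differences are theta-specific. Coupling strengths
are jittered per subject (SD 0.04), and the theta coupling deficit
(control strength minus the subject's realized strength) drives
behavior: executive time = 75.93 + 106·deficit + N(0, 15²) seconds and
a Poisson error count with rate 0.31 + 2.6·deficit, placing the group
means near 76 vs 124 s.

The strengths sit deliberately high: at 10-s/250-Hz epochs the 100-bin
MI estimator is compressed below pair correlations of ~0.6, and the
common-average reference absorbs part of any shared signal, so coupled
pairs must be strongly correlated for their nMI to rise visibly above
the bias floor — as they are in real volume-conducted EEG, where
neighboring-channel correlations are routinely this large. With these
defaults the coupled pairs land where the absolute-threshold sweep
(0.15–0.45) has an informative region.

What the generator does **not** model: volume-conduction leadfields,
ocular/muscle artifacts, nonstationarity across epochs, and
phase-coupled oscillators (sources are linearly mixed Gaussian
processes — MI detects any dependence, so linear coupling suffices to
exercise the estimator). Passing parameter-recovery tests therefore
demonstrates that the pipeline detects the designed kind of
band-specific coupling difference at study scale; it does not certify
performance on artifacts or nonlinear coupling regimes.

## Problem sizes, determinism, numerics

The validation suite runs the full parameter-recovery loop (generate →
preprocess → MI → OMST → L → U-test) 20 times at the default cohort
scale, theta band only — the band carrying the designed effect; the
other bands are exercised by the unit tests and the full-pipeline
driver. Small-world indices use 300 nulls. Simulations default to
250 Hz (1000 Hz available by config) and 60 s per subject; these sizes
were chosen to keep a complete desk-scale replication in minutes while
preserving the 14 + 14 design.

All randomness flows from numpy Generators; the pipeline derives
per-stage and per-subject child seeds from the root seed with
`SeedSequence` over CRC32-hashed labels, so reruns are byte-identical
and stages are independently reproducible. Tie-breaks (mean-degree
cutoffs, MST construction order) are lexicographic. Degenerate inputs
have defined behavior: constant signals (zero entropy → nMI 0), empty
graphs (L is an error), K too small for any edge (error), disconnected
weighted graphs under OMST (error naming the components).

## Known limitations

Binary graphs discard weight information beyond rank; the histogram MI
estimator's bias floor limits sensitivity at low sampling rates; the
degree-preserving null does not control clustering beyond what the
degree sequence implies; and the default T grid can empty synthetic
graphs at its upper end (recorded as undefined-L sweep points rather
than data).
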
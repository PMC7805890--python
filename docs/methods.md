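# Methods

## The tracking model

`barntrack` tracks multiple animals on a discrete state grid directly from
per-state detection likelihoods, without ever committing to a finite set of
detections.  A state is `s = (x, y, α)`: a cell on the metrically uniform
shoulder plane (default 0.1 m cells over a 6 × 18 m waiting area) plus one of
`n_orient` orientation bins.  The observation at frame `t` is a map
`d_{s,t} ∈ [0, 1]`, the likelihood that some animal occupies state `s` — in
the original system the output of an orientation-aware CNN detector, here
produced by the scene simulator.  No non-maximum suppression is applied: the
tracker consumes the full map.

For every state the tracker maintains the identity `o_{s,t}` of the object
most likely to occupy it (or a background sentinel) and the probability
`p_{s,t}` that this object is in `s`.  One frame of tracking is the
recursion

1. `e_s = argmax_ŝ  p_{ŝ,t−1} · p(s | ŝ)` — most likely predecessor,
2. `o_{s,t} = o_{e_s,t−1}` — ownership propagates along the argmax,
3. `p̃_{s,t} = d_{s,t} · p_{e_s,t−1} · p(s | e_s)` — raw probability,
4. `p_{s,t} = p̃_{s,t} / Σ_{ŝ: o_{ŝ,t}=o_{s,t}} p̃_{ŝ,t}` — per-object
   normalization,
5. `s_o = argmax_{s: o_{s,t}=o} p_{s,t}` — per-object MAP state.

Ownership being single-valued per state structurally enforces that two
objects cannot share a state.  The per-object normalization assumes each
object is still present and located in one of the states it currently owns;
this is an approximation that is immaterial for well-separated animals and
is exactly where the method's failure mode (identity confusion in crowded
scenes) lives.

The motion model `p(s_t | s_{t−1})` is a discrete truncated Gaussian with
bounded support, normalized over the full support box before border
truncation:

| parameter | default | meaning |
|---|---|---|
| `pos_radius` | 2 cells | max displacement per axis per frame (0.2 m/frame = 3.2 m/s at 16 FPS — above any walking cow) |
| `sigma_pos` | 1.0 cell | spatial spread per frame |
| `orient_radius` | 2 bins | max orientation change per frame |
| `sigma_orient` | 1.0 bin | orientation spread per frame |

A zero sigma degenerates to a point mass.  Orientation displacements use
the shortest signed wrap (ties at half the circle toward positive).  At the
grid borders the kernel is truncated **without** renormalization — the
single biggest free design choice.  The recursion uses transition
probabilities only inside one argmax and one product, and step 4
renormalizes per object, so only probability *ratios* matter; truncation
loses a little mass for border states but keeps the kernel table identical
everywhere, which keeps the separable fast path exact.  Whether the
original system renormalized at borders is not determinable; the choice is
isolated in one place.

Both argmaxes break ties toward the smallest flat state index
(`(y·n_x + x)·n_orient + α`), making runs bit-for-bit reproducible.
Arithmetic stays in the linear domain: detection maps are floored at
`ε_d = 1e−6` (an exact zero would lock a state out of the multiplicative
recursion forever), and the per-frame per-object normalization bounds the
dynamic range, which an overflow stress test confirms.

### Implementation of the hot path

The per-frame step is a max-product dilation with the kernel.  For
Gaussian-built kernels the kernel factorizes per axis, so the argmax runs
as three numba-compiled passes (orientation, x, y), each keeping the
smallest-index winner; nesting the passes y-outer/x-middle/orientation-inner
reproduces the global lexicographic tie-break exactly.  Hand-specified
kernels take a generic dense scan over the displacement support.  Both
paths are verified against a brute-force enumeration of all state pairs
(1000 random instances, exact ownership/predecessor agreement, probability
agreement to 1e−12).  On the 60 × 180 × 8 grid one frame costs ~4 ms on one
CPU core.

## Gates, identity, and lifecycle

Animals enter and leave through RFID selection gates bound to grid cells.
An entry registration instantiates a new object with probability one at the
gate state `s_in`; an exit registration removes the object most likely to
be at `s_out` (the owner of the gate state, or — if the gate state is
background — the live object with the largest mass in the kernel
neighbourhood of the gate, ties toward the smallest object id).  Between
events the number of live objects is constant.  An object whose total mass
vanishes is flagged *lost*, keeps its last estimate, and is never
resurrected — once a track is lost it is very unlikely to be recovered, so
resurrection is out of scope.

Entry instantiation additionally clears the kernel-support neighbourhood of
the gate cell (all orientations): the entering animal's body physically
occupies the gate area, so probability mass that another object keeps
parked there — typically a phantom track held at the gate by the synthetic
observations below — is displaced, with the dispossessed object
renormalized over its remaining states.  Without this, the parked mass
renormalizes onto the ring around the gate and reliably captures the
newcomer's detections (diagnosed on failing synthetic seeds; the
single-state instantiation is the `clear_radius=0` case).

*Synthetic gate observations*: every frame, the detection value at each
gate state is raised to at least `synthetic_prob = 0.05` (never lowered, so
the operation is idempotent).  This holds a track at the gate during the
interval between the registration and the animal being fully visible.  The
value must exceed `ε_d` by a wide margin yet stay far below real detection
peaks; injection happens every frame, which subsumes the narrower reading
of injecting only between registration and appearance.

*Exit criterion*: alternatively to gate-driven removal (`exit_mode="gate"`),
the tracker can detect exits itself (`exit_mode="criterion"`): when an
object's MAP state equals one exit gate's state for strictly more than
0.5 s of consecutive frames — `floor(0.5·fps)+1 = 9` frames at 16 FPS,
reading "more than" strictly — it is removed, with the exit timestamped at
the first frame of the dwell.  In this mode the gate exit registrations are
withheld from the tracker and used purely for scoring.

*Time reversal*: exit registrations are better timed than entry
registrations (a physical exit gate fires only once the animal has left,
and one entry gate may lie outside the camera view), so a recording can be
played backwards with entry and exit roles swapped.  Reversal maps frame
`f → n_frames−1−f` and recomputes timestamps from the mapped frame, which
makes double reversal an exact involution (a `T − t` time map would be off
by one frame at the boundaries).  Animals present at the start of the
reversed sequence are marked by the caller with synthetic ids.

*Identity back-tracing*: each object instantiated by an entry registration
carries that registration's animal id along its whole track, back to its
first frame.  Registrations are matched to tracks by (frame, gate);
simultaneous registrations at one gate pair with the objects they
instantiated in instantiation order, and a registration with no matching
track is a data error.  Manually marked initial objects keep their
synthetic ids.

## Camera geometry

Cameras are classical pinholes with two radial distortion coefficients
(`x_d = x_u(1 + k1·r² + k2·r⁴)`; tangential terms omitted — the distortion
model of the original system is not parameterized anywhere, so radial-2 is
an assumption).  Undistortion inverts the model by fixed-point iteration to
a 1e−10 residual, failing loudly after 100 iterations.  The homography onto
the shoulder plane (z = 1.49 m, the mean of 12 measured animals, SD
0.05 m) is estimated from ≥ 4 marker correspondences by the normalized DLT;
rank deficiency (collinear markers) raises an error.  Orientation bins are
mapped through the local Jacobian of the homography.  Detections from
overlapping cameras within `merge_radius_m = 0.5` (about half a cow width;
no threshold is documented for the original system) and within 2
orientation bins merge greedily in deterministic (camera, index) order into
their weight-weighted centroid with the maximum member weight.

## The scene simulator

The simulator replaces the barn and the CNN detector; its defaults are the
study conditions used throughout the tests: a 6 × 18 m waiting area at
16 FPS, 0.1 m cells, 8 orientation bins, 180 s recordings, 5 cows, one
entry gate on the far wall and four milking-station exit gates along the
near wall.  Eight orientation bins (rather than the detector convention of
32) keep the full-scale state count at 86,400; the grid resolution itself
is a free choice — the original system's granularity is its CNN output
stride, which is not published.

Cows enter on a Poisson-like schedule (exponential gaps, at least 4 s
apart — a physical selection gate passes one animal every few seconds, and
by then the previous animal has walked clear of the gate's detection
footprint), perform a correlated random walk (Ornstein–Uhlenbeck speed with
mean 0.45 cells/frame ≈ 0.7 m/s, capped at 0.8 cells/frame so grid
displacements stay within one cell per axis; heading follows the walk with
turn rate capped below one orientation bin per frame), and after a dwell
period steer to a uniformly chosen exit gate, logging the exit when they
reach its cell.  Collision avoidance acts at body scale: soft repulsion
plus a hard non-approach constraint at 0.6 m (a cow's width) with
tangential sliding.  Point-agents with sub-body separations produce
identity-swap scenes that physically cannot occur, which is why the radius
is a physical length rather than one grid cell.

Detection rendering: per frame and cow, with probability `detect_prob` a
Gaussian bump of peak 0.9 (realistic detector confidence, and separable
from the 0.05 synthetic gate observations) and spatial width
`peak_sigma_cells` is max-composited at the true state; Poisson clutter
bumps of weight `clutter_weight` appear at uniform states; everything is
clamped to `[ε_d, 1]`.  All randomness flows from one seeded generator —
equal seeds give byte-identical scenes and maps.

What the simulator does *not* emulate: occlusion and partial visibility,
correlated or structured clutter (false detections in real barns cluster
on gates, shadows and railings), detector confidence drift with lighting,
body extent (a cow is a point with an orientation), and behavioural
interactions.  Passing synthetic tests therefore demonstrates the
correctness and noise robustness of the *tracking recursion*, not detector
performance on real video.

A measured robustness property worth stating: transient uniform clutter up
to 1 bump/frame at weight 0.8 has no detectable effect on exit-gate
accuracy at the study conditions — an object's probability at a random
clutter site is essentially zero, so clutter competes only during missed
detections.  The degradation test therefore checks the *direction* of the
clutter effect with a binomial sampling-error allowance rather than strict
ordering of sample means, which a flat curve cannot reliably satisfy.

## Evaluation protocol

A track is *correct* when its exit gate matches the RFID-registered exit
gate and the exit-time difference is at most 60 s (one physical gate sat
outside the camera view, so even correct exits can differ by up to a
minute).  Durations are accounted per track: correct tracks contribute
their full length, failed tracks only their correctly-tracked portion.
Against synthetic ground truth that portion runs until the estimate strays
more than 3 cells (0.3 m) from the true position for more than 0.5 s —
single-frame glitches are per-frame detection failures, not track failures.
Without ground truth, correct tracks count in full and failed tracks
contribute zero (the bundled benchmark's failed-track portions came from
manual inspection and are stored verbatim).

The bundled benchmark (26 tracks from one easy and one crowded hour of
barn recording) reproduces: 23 of 26 tracks correct, 101.29 min correctly
tracked in total, longest correct track 20.67 min.  The mean is reported
as total/26 = 233.8 s; dividing by 27 would give ≈ 225 s, and the
discrepancy between those two conventions in the source material is
recorded, not resolved.

## Problem sizes used in the test suite

Full-scale synthetic checks run the complete study condition (5 cows,
180 s, 2,880 frames, 86,400 states): exact noiseless recovery once, and the
noise-robustness study over 20 seeds (measured: 94% of registered exits
assigned the correct gate at detection rate 0.95, 1-cell blur, 0.2 clutter
bumps/frame; the residual failures are genuine identity-confusion cases of
the method).  The oracle-equivalence property uses 1000 random instances
with at most 200 states, where brute-force enumeration is affordable.  The
degradation study uses 90 s, 4-cow scenes so that three clutter levels
times 20 seeds stay within an ordinary test run.

## Known limitations

* Identity confusion between animals closer than the detection-bump
  overlap scale is inherent to per-state exclusive ownership with
  per-object normalization; the original study observes the same in
  crowded scenes.
* A phantom object (one that lost its animal) parks at the nearest
  synthetic gate observation; entry-neighbourhood clearing handles the
  entry gates, but phantoms elsewhere persist until an exit event removes
  them.
* Border truncation without renormalization slightly biases border states
  toward lower scores.
* The 0.5 s exit dwell assumes the exit gate state is reachable by the
  MAP estimate; with orientation-specific exit gates and heavy orientation
  noise the criterion can fire late.
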
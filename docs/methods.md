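# Methods

## The model

Tethered DNA structures are coarse-grained as linear chains of domains
anchored at a fixed tether coordinate on the tile surface, taken as the
`z = 0` plane with `z` increasing away from the tile.  Bond lengths
between complementary bases are treated as zero, so a conformation is
fully described by one coordinate per joint: the tether, each
inter-domain junction, and the strand terminus.

Double-stranded domains are rigid rods of length `n_nt × 0.34 nm`.
Single-stranded domains have contour length `L = n_nt × 0.68 nm` and a
random end-to-end length, drawn either uniformly on `[0, L]` (treating
the strand as infinitely flexible) or from the worm-like-chain (WLC)
end-to-end density for persistence length `s = 2 nm`,

    p(R) = (1/L) · 4πA r² (1 − r²)^(−9/2) exp(−3t / (4(1 − r²))),
    A = 4 a^(3/2) e^a / [π^(3/2)(4 + 12/a + 15/a²)],   a = 3t/4,

with `t = L/s`, `r = R/L`.  The WLC option biases the strand toward
elongation relative to the uniform model.

Joint deviation angles depend on the joint type.  Directions built from
a uniform polar angle would cluster at the poles, so polar angles are
drawn as `arccos(2x − 1)` with `x ~ U(0,1)` (full sphere) or
`arccos(x)` (upper hemisphere, used for the tether joint — the
measure-preserving restriction to the half-space above the tile).  The
angle at a nick between two duplexes either uses the same full-sphere
rule (uniform variant) or is drawn from an empirical histogram (nicked
variant), reflecting coaxial stacking that keeps the two duplex arms
roughly aligned.  The four model names combine these choices:
UU/UN/WU/WN = {uniform, WLC} ss lengths × {uniform, nicked} nick angle.

## Chain growth

Conformations are grown from the tether outward.  The first direction
comes from a hemisphere polar draw plus a uniform azimuth about `+z`.
Each subsequent direction is sampled on the rim of the cone of
half-angle φ around the previous unit direction `v`: the rim is the
circle with centre `v(1 + cos φ)` and radius `sin φ` in the plane of an
orthonormal pair `(a, b) ⟂ v`; a uniform angle θ picks a rim point `p`,
and `u = p − v` is the next unit direction, satisfying `u · v = cos φ`
exactly.  The orthonormal pair is built by fixing the two components of
`a` not matching `v`'s largest-magnitude component to 1, solving the
orthogonality equation for the remaining component, normalizing, and
taking `b = a × v`.  Joint coordinates are the tether plus the running
sum of `length_k · u_k`.

Conformations with any post-tether joint at `z ≤ z_floor` are rejected
wholesale and regrown.  The default `z_floor = 0` enforces only the
tile-surface constraint; a positive value is a crude proxy for
electrostatic repulsion from the charged tile surface.  The tether
itself lies on the plane and is exempt from the test.  Equality
(`z = z_floor` exactly) is rejected — a measure-zero choice made for
definiteness.  A cap of 10⁴ consecutive rejections guards against
configurations whose acceptance region is unreachable (e.g. a `z_floor`
above the chain's maximum reach); hitting the cap raises a diagnostic
error rather than looping.  `z_floor = −inf` disables the surface test
entirely and exists only for diagnostic distribution checks.

Before sampling, structure specs are simplified: domains distal to the
reactive toehold are removed (they cannot move the toehold), and
adjacent same-kind domains are condensed by summing nucleotide counts —
except across backbone nicks (a real joint, marked with `nick_after`)
and except the reactive toehold itself, both of whose endpoints are
needed to place the reactive point (the toehold midpoint).

## Numerical choices

- **WLC sampling** uses inverse-transform sampling on a tabulated CDF:
  4096 uniform grid points on `[0, L(1 − 10⁻⁶)]`, cumulative trapezoid
  integration, linear interpolation of the inverse.  The density is
  clipped at `r = 1 − 10⁻⁶`; the exponential factor makes the clipped
  tail mass negligible (the density integrates to 1 within 10⁻³ across
  `t ∈ [0.5, 20]`, verified by adaptive quadrature).  The method of the
  original description is not stated; inverse-CDF was chosen here for
  deterministic accuracy with no rejection-rate pathologies near full
  extension.
- **Hemisphere draws** use `x = 1 − U[0,1) ∈ (0, 1]` so the support
  excludes the tile plane itself.
- **Neighbour counting** bins points into cubic cells whose width
  equals the colocation threshold; all neighbours of a query then lie
  in its cell or the 26 adjacent ones, and counts are integer-exact
  against brute force (distance comparison inclusive, `d ≤ threshold`).
  Other bin widths are rejected rather than silently widened, since the
  27-cell completeness argument requires equality.  The vectorized
  estimator groups queries by cell and uses the same
  difference-and-square arithmetic as the scalar path.
- **Aggregation**: query points with zero neighbours contribute `C = 0`
  to the mean — dropping them would bias the estimate upward.  The
  perspective (which ensemble is observed from which) is arbitrary;
  both directions give identical means and the swap is exposed as an
  option.
- **Units**: `C = P/V` in particles/nm³ is converted to mol/L by
  `10²⁷ / (6.022 × 10²³ × 1000) ≈ 1.6606 M per particle/nm³`.
  Machine output reports nM.
- **Reproducibility**: one `numpy` Generator is threaded through all
  samplers; identical seed and configuration give bit-identical
  ensembles.  Replicate seeds derive from the master seed via
  `SeedSequence.spawn`, so replicate summaries are reproducible.
  The batched ensemble sampler and the single-draw path consume
  the stream in different orders; each is individually deterministic.

## The fixture and its stand-ins

The built-in two-structure fixture emulates a tethered hairpin signal
wire: `H0` (two rigid duplex arms joined at a nick, ending in an exposed
6-nt ss toehold) tethered at the origin, and `H1` (ss spacer + 6-nt
complementary toehold) tethered at `(0, d, 0)` with `d = 10.88 nm` by
default and `21.76 nm` as the doubled-spacing negative control.

Two inputs of the real experimental system are not available here and
are shipped as documented stand-ins:

- **Domain lengths** `d0 = d1 = 16 nt`, `spacer = 5 nt` — plausible
  condensed-arm and spacer sizes, not measured values.  Override via
  the fixture's `lengths` table to model a real design.
- **Nick-angle histogram** — the real distribution must be measured
  from coarse-grained MD trajectories of the actual construct.  The
  shipped `standin_nick_histogram()` is synthetic: mass on 10–40° with
  its mode in 20–30°, reproducing only the qualitative stacking
  picture.  File-based override (`--nick-histogram`) is the supported
  path to fidelity, and nicked-model runs without any histogram are a
  configuration error rather than a silent fallback.

Consequences worth knowing: with the stand-in lengths the two
structures' maximum combined reach (≈ 18.4 nm) falls short of the
doubled spacing minus the threshold, so the negative control evaluates
to exactly zero local concentration instead of a small positive value;
and the absolute concentrations at 10.88 nm (≈ 300 µM under WN) are
specific to the stand-ins, though they land in the experimentally
plausible range of tens to hundreds of µM for such wires.  What the
passing tests demonstrate is the correctness of the machinery —
distributional fidelity of the samplers, exact geometry of the cone
construction, exact neighbour counts, exact unit conversion, monotone
distance attenuation, and 1/√n replicate convergence — not the absolute
rate of any particular laboratory construct.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| `len_per_nt_ds` | 0.34 | nm/bp | duplex rise |
| `len_per_nt_ss` | 0.68 | nm/nt | ss contour length |
| `persistence_ss` | 2.0 | nm | WLC models only |
| `threshold` | 2.0 | nm | colocation radius and hash cell width |
| `k_bi` | 5 × 10⁵ | M⁻¹s⁻¹ | 6-nt toehold association reference |
| `z_floor` | 0 | nm | surface-exclusion height ε |
| `n_samples` | 10⁵ | — | per ensemble; SD across replicates ~1/√n |
| `replicates` | 5 | — | for mean ± SD summaries |

10⁵ samples per ensemble is the default compromise between estimate
stability (replicate SD ≈ 1.5 % of the mean at the standard spacing)
and runtime (a full five-replicate, two-distance run completes in well
under a minute on one CPU).

## Known limitations

- No excluded volume within or between structures, and no steric
  interaction with the tile beyond the z-constraint; ensembles of the
  two structures are sampled independently.
- Joints only are tested against the surface; a rigid rod could in
  principle pass through the tile between two above-surface joints.
- Linear chains with a single tether only; branched structures and
  multi-tether constraints are out of scope.
- No sequence-dependent flexibility, temperature or salt dependence;
  the toehold-binding step only (downstream branch migration is not
  modelled).
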
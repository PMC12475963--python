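# Methods

`barrierless` estimates Gibbs free-energy barriers for reactions whose
electronic energy rises monotonically along the dissociation coordinate —
"barrierless" or diffusion-controlled processes with loose, entropy-dominated
transition states.  Static electronic-structure output (a relaxed scan, a
bond-strength descriptor along the scan, and endpoint frequencies) is turned
into a continuous free-energy curve whose interior maximum is the barrier.
This note records the model, its assumptions, the tunable parameters, the
numerical choices, and what the synthetic test bed does and does not show.

## Model

**Electronic energy.** The scanned electronic energies, referenced so the
separated fragments sit at exactly 0 kJ/mol, are condensed into a Morse
potential

    dE(r) = De * [ exp(-2a(r - r_eq)) - 2 exp(-a(r - r_eq)) ]

with well depth `De > 0` (kJ/mol), decay `a` (1/Å) and equilibrium bond
length `r_eq` (Å), so that `dE(r_eq) = -De` and `dE -> 0` as `r -> inf`.
All three parameters are obtained by nonlinear least squares
(`scipy.optimize.curve_fit`); `r_eq` may instead be held at the optimized
geometry's value (`fix_r_eq`), since either convention appears in practice.

**Bond cleavage.** A quantum-chemical bond-strength descriptor (IBSI, Mayer
or Laplacian bond order, or an AIM critical-point property such as ELF, LIE
or LED) is computed externally at every scan step, min-max normalized to
[0, 1] and fitted with a single exponential `D_fit(r) = D0 exp(-k_desc r)` in
the absolute bond distance.  The bond is deemed broken at the first distance
where the magnitude of the fitted slope falls to a cutoff `gamma_cleave`:

    r_cleave = ln(k_desc * D0 / gamma_cleave) / k_desc .

Because the slope magnitude `k_desc*D0*exp(-k_desc r)` is strictly
decreasing, `r_cleave` is strictly decreasing in `gamma_cleave`: a looser
cutoff breaks the bond earlier.  If the slope is already below the cutoff at
the scan start, the input is rejected ("bond already broken at
equilibrium").

**Entropy onset.** The total entropy change of dissociation is taken from
rigid-rotor/harmonic-oscillator (RRHO) ideal-gas thermochemistry of the three
endpoint species only: the amplitude `A = -T*(S_A + S_B - S_AB)` (kJ/mol,
negative when entropy is gained).  Along the coordinate the entropy is
switched on by a logistic function anchored at the cleavage distance,

    -T dS(r) = A / (1 + exp(-k_sig (r - r_cleave))) ,

so that exactly half the amplitude is recovered at `r_cleave` — the central
physical assumption: a broken bond has released half of the final
translational/rotational entropy gain.  The logistic form is used literally;
its value at `r_eq` is small but nonzero, is reported in the result metadata
(`sigmoid_residual_at_r_eq`), and can be subtracted from the reported curve
with `offset_at_req` (the barriers are differences against references that
shift with the curve, so they do not change).

**Assembly and barriers.**  `dG(r) = dE(r) + (-T dS(r))`.  The global
interior maximum beyond `r_eq` is the loose transition state;
`barrier_dissociation = dG(r_ts) - dG(r_eq)` and
`barrier_association = dG(r_ts) - A` (the infinite-separation asymptote is
the natural zero of an association profile).  If the interior maximum exceeds
neither reference by more than `tol_barrier`, the run reports the explicit
no-barrier outcome — a legitimate result, observed for small cleavage cutoffs.

**Steepness tuning.**  A too-steep sigmoid saturates before the Morse tail
has flattened, producing an artificial minimum after the transition state
(the curve dips and then climbs back to the asymptote wherever
`k_sig` exceeds the Morse decay scale).  Starting from `k_start` the
steepness is therefore multiplied by `shrink` until the curve, scanned at
`grid_step` over the evaluation window, has no interior local minimum beyond
the transition state whose subsequent rise exceeds `tol_min`.  The first
(largest) accepted `k_sig` is returned, so one step back (`k_sig/shrink`)
would re-create the dip.  Reaching `k_floor` without success is an error.

## Parameters

| parameter | unit | default | rationale |
|---|---|---|---|
| `gamma_cleave` | 1/Å (normalized descriptor per Å) | 0.02 | cutoff on the descriptor slope; ~0.02 is adequate for gas-phase reactions at moderate temperatures, ~0.01 for solution-phase organometallics; always sweep it (`--gamma-sweep`) and use one value across the steps of a profile |
| `temperature` | K | 298.15 | standard conditions; RRHO reliability degrades far above ~1200 K |
| `pressure` | Pa | 101325 | gas-phase standard state, no concentration correction |
| `raising_cutoff` | cm^-1 | 100 | quasi-harmonic raising of soft modes before the vibrational entropy sum (GoodVibes-style); 0 recovers the plain harmonic result |
| `k_start` | 1/Å | 10 | initial sigmoid steepness |
| `shrink` | — | 0.9 | geometric decrease per tuning step |
| `k_floor` | 1/Å | 0.1 | below this the tuning aborts |
| `tol_min` | kJ/mol | 0.01 | depth a post-TS dip must rise by to count as a minimum |
| `tol_barrier` | kJ/mol | 0.01 | margin above a reference for a real barrier |
| `grid_step` | Å | 1e-3 | resolution of barrier/dip detection before parabolic refinement |

The tuning schedule (10, x0.9, floor 0.1) closes a gap the method itself
leaves open — only "iteratively decrease from about 10" is physically
motivated — and every element of it is configurable.

## Numerical choices

- Energies are stored in kJ/mol with the separated-fragment asymptote at
  exactly 0; Hartree input is converted with 1 Eh = 2625.499639 kJ/mol.
- Morse initial guesses: `r_eq` at the scan minimum, `De = -E_min`, decay
  from the half-depth crossing of the outer wall
  (`a ~ 1.2279/(r_half - r_eq)`); descriptor seed from a log-linear
  regression on values above 1e-6.  `curve_fit` runs with 1e-14 tolerances so
  noiseless synthetic inputs are recovered to better than 1e-6 relative.
- The transition state is located on a `grid_step` grid over
  `[r_eq, max(scan end, r_cleave + 10/k_sig)]` — wide enough that both the
  Morse tail and the sigmoid are saturated — then refined with a three-point
  parabola (refinement is clamped to one grid cell and never accepted if it
  lowers the grid maximum).
- Rotational entropy treats a species as a linear rotor when its smallest
  principal moment of inertia is below 1e-3 amu·Å^2; symmetry numbers are
  user-supplied, never perceived from the geometry.  Standard atomic weights
  (not single-isotope masses) enter the mass and inertia calculations.
- Imaginary frequencies abort the entropy calculation unless explicitly
  discarded (`discard_imaginary`), in which case they are dropped with a
  warning.
- Min-max normalization of a finite exponential series subtracts its small
  tail value, so the normalized series is not exactly exponential; the fit
  redistributes that offset.  The synthetic oracle therefore derives its
  reference cleavage distance by independently fitting (iterative grid
  search) the exactly normalized noiseless series, rather than by rescaling
  the generating parameters.

## Synthetic test bed

The `synthetic` module generates complete inputs with known ground truth:
Morse energies and an exponentially decaying descriptor on a 0.05 Å grid
(mirroring common relaxed-scan protocols), i.i.d. Gaussian noise with seeded
reproducibility, and amplitudes drawn from the typical -20 to -50 kJ/mol
band of small-molecule dissociation entropies at room temperature.
`analytic_barrier` composes the exact free-energy curve from the true
parameters and maximizes it by brute force on a 1e-4 Å grid; the pipeline
reproduces it to ~1e-3 kJ/mol on noiseless cases and to well under
0.5 kJ/mol median error at 0.1 kJ/mol energy noise.

What this does **not** show: real scans are not exactly Morse-shaped (the
fit quality should be checked through the reported residual sum of squares),
real descriptors deviate from a single exponential, relaxed scans can hop
between electronic states or conformers, and the RRHO endpoint entropies
inherit all harmonic-approximation limitations.  Gaussian noise is a minimal
stand-in for such structure-less scatter, not a model of those systematic
effects.

## Limitations

- One-dimensional reaction coordinate; no variational optimization of the
  dividing surface, no tunneling, no recrossing.
- Entropy interpolation rests on the 50%-at-cleavage assumption and on a
  single descriptor; different descriptors (and different `gamma_cleave`)
  give systematically different barriers, so cutoffs must be held fixed when
  comparing reactions.
- RRHO endpoints: no hindered-rotor, free-volume, or conformational-entropy
  corrections; results at very high temperature (above roughly 1200 K) are
  unreliable.
- The descriptor fit assumes monotone exponential decay; descriptors that
  plateau or oscillate along the scan are rejected as unsuitable.
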
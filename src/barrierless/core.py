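"""Free-energy barrier construction for electronically barrierless dissociations.

A relaxed-scan electronic dissociation curve is condensed into a Morse
potential

    dE(r) = De * (exp(-2a(r - r_eq)) - 2 exp(-a(r - r_eq)))

whose asymptote coincides with the separated-fragment reference (dE -> 0 as
r -> inf, dE(r_eq) = -De).  A normalized bond-strength descriptor along the
same scan is fitted with a single exponential D0*exp(-k_desc*r); the bond is
deemed cleaved at the first distance r_cleave where |dD_fit/dr| falls to the
cutoff gamma_cleave, which has the closed form

    r_cleave = ln(k_desc * D0 / gamma_cleave) / k_desc.

The entropy of dissociation is switched on by a sigmoid anchored at
r_cleave, where exactly half of the total amplitude -T*(S_A + S_B - S_AB)
is recovered:

    -T dS(r) = A / (1 + exp(-k_sig * (r - r_cleave))).

The Gibbs curve is the pointwise sum dG(r) = dE(r) - T dS(r); its interior
maximum beyond r_eq is the loose transition state.  A too-steep sigmoid
produces an artificial minimum after that maximum, so k_sig is lowered
geometrically from its start value until the curve decays monotonically
past the transition state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .scan_io import DescriptorSeries, DissociationScan


class FitError(RuntimeError):
    """A least-squares fit failed or its input is inconsistent with the model."""


class TuningError(RuntimeError):
    """The sigmoid steepness search hit its floor without removing the dip."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


# defaults of the steepness search and barrier detection (all overridable)
K_START = 10.0        # Å^-1, initial sigmoid steepness
K_SHRINK = 0.9        # multiplicative decrease per iteration
K_FLOOR = 0.1         # Å^-1, give up below this
TOL_MIN = 0.01        # kJ/mol, depth a post-TS dip must rise by to count
TOL_BARRIER = 0.01    # kJ/mol, margin above a reference for a real barrier
GRID_STEP = 1e-3      # Å, resolution of barrier/dip detection grids


# ---------------------------------------------------------------------------
# model types
# ---------------------------------------------------------------------------

@dataclass
class MorseFit:
    """Morse parameters: well depth De > 0 (kJ/mol), decay a (Å^-1), r_eq (Å)."""

    well_depth: float
    decay: float
    r_eq: float
    rss: float = 0.0

    def predict(self, r) -> np.ndarray:
        d = np.asarray(r, dtype=float) - self.r_eq
        return self.well_depth * (np.exp(-2.0 * self.decay * d)
                                  - 2.0 * np.exp(-self.decay * d))


@dataclass
class DescriptorFit:
    """Exponential descriptor decay D0 * exp(-k_desc * r) of the normalized series."""

    d0: float
    k_desc: float
    rss: float = 0.0

    def predict(self, r) -> np.ndarray:
        return self.d0 * np.exp(-self.k_desc * np.asarray(r, dtype=float))

    def slope(self, r) -> np.ndarray:
        return -self.k_desc * self.predict(r)


@dataclass
class CleavagePoint:
    """Bond-cleavage distance: first r with |dD_fit/dr| <= gamma_cleave."""

    gamma_cleave: float
    r_cleave: float


@dataclass
class EntropySigmoid:
    """Sigmoid entropy model A / (1 + exp(-k_sig (r - r_cleave))).

    ``amplitude`` is -T*(S_A + S_B - S_AB) in kJ/mol (negative for entropy
    gain); the inflection point r_cleave carries exactly half the amplitude.
    """

    amplitude: float
    r_cleave: float
    k_sig: float

    def predict(self, r) -> np.ndarray:
        x = -self.k_sig * (np.asarray(r, dtype=float) - self.r_cleave)
        return self.amplitude / (1.0 + np.exp(x))


@dataclass
class FreeEnergyResult:
    """Assembled Gibbs curve and, once located, the loose TS and barriers.

    ``barrier_dissociation`` is dG(r_ts) - dG(r_eq); ``barrier_association``
    is dG(r_ts) minus the infinite-separation asymptote (the amplitude),
    which is the zero of association free-energy profiles.
    """

    grid_r: np.ndarray
    delta_g: np.ndarray
    morse: MorseFit
    sigmoid: EntropySigmoid
    k_sig_final: float
    r_ts: float | None = None
    barrier_dissociation: float | None = None
    barrier_association: float | None = None
    no_barrier: bool = False
    descriptor_fit: DescriptorFit | None = None
    cleavage: CleavagePoint | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid_r = np.asarray(self.grid_r, dtype=float)
        self.delta_g = np.asarray(self.delta_g, dtype=float)

    def to_dict(self) -> dict:
        return {
            "morse": vars(self.morse),
            "descriptor_fit": vars(self.descriptor_fit) if self.descriptor_fit else None,
            "cleavage": vars(self.cleavage) if self.cleavage else None,
            "sigmoid": vars(self.sigmoid),
            "k_sig_final": self.k_sig_final,
            "r_ts": self.r_ts,
            "barrier_dissociation": self.barrier_dissociation,
            "barrier_association": self.barrier_association,
            "no_barrier": self.no_barrier,
            "grid_r": self.grid_r.tolist(),
            "delta_g": self.delta_g.tolist(),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FreeEnergyResult":
        return cls(
            grid_r=np.asarray(doc["grid_r"], dtype=float),
            delta_g=np.asarray(doc["delta_g"], dtype=float),
            morse=MorseFit(**doc["morse"]),
            sigmoid=EntropySigmoid(**doc["sigmoid"]),
            k_sig_final=doc["k_sig_final"],
            r_ts=doc["r_ts"],
            barrier_dissociation=doc["barrier_dissociation"],
            barrier_association=doc["barrier_association"],
            no_barrier=doc["no_barrier"],
            descriptor_fit=DescriptorFit(**doc["descriptor_fit"])
            if doc.get("descriptor_fit") else None,
            cleavage=CleavagePoint(**doc["cleavage"]) if doc.get("cleavage") else None,
            metadata=doc.get("metadata", {}),
        )


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def fit_morse(scan: DissociationScan, fix_r_eq: float | None = None) -> MorseFit:
    """Least-squares Morse fit of a dissociation scan.

    Energies must be referenced to 0 at infinite separation (a bound well is
    negative).  With ``fix_r_eq`` the equilibrium distance is held fixed and
    only (well depth, decay) are optimized.
    """
    r, e = scan.distances, scan.energies
    i_min = int(np.argmin(e))
    e_min = e[i_min]
    if e_min >= 0.0:
        raise FitError(
            "scan has no bound well: minimum energy is not below the "
            "separated-fragment reference (0)")
    if i_min == len(e) - 1:
        raise FitError(
            "scan energy is still decreasing at the largest distance; "
            "inconsistent with a bound Morse well")
    de0 = -e_min
    req0 = fix_r_eq if fix_r_eq is not None else float(r[i_min])
    a0 = _initial_morse_decay(r, e, req0, de0)

    if fix_r_eq is None:
        def model(x, de, a, req):
            d = x - req
            return de * (np.exp(-2 * a * d) - 2 * np.exp(-a * d))
        p0 = [de0, a0, req0]
        bounds = ([1e-12, 1e-12, r[0] - 1.0], [np.inf, np.inf, r[-1] + 1.0])
    else:
        def model(x, de, a):
            d = x - fix_r_eq
            return de * (np.exp(-2 * a * d) - 2 * np.exp(-a * d))
        p0 = [de0, a0]
        bounds = ([1e-12, 1e-12], [np.inf, np.inf])

    try:
        popt, _ = curve_fit(model, r, e, p0=p0, bounds=bounds, maxfev=20000,
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except RuntimeError as exc:
        raise FitError(f"Morse fit did not converge: {exc}") from exc
    rss = float(np.sum((model(r, *popt) - e) ** 2))
    if not np.isfinite(rss):
        raise FitError("Morse fit produced non-finite residuals")
    if fix_r_eq is None:
        return MorseFit(float(popt[0]), float(popt[1]), float(popt[2]), rss)
    return MorseFit(float(popt[0]), float(popt[1]), float(fix_r_eq), rss)


def _initial_morse_decay(r, e, req0, de0) -> float:
    """Heuristic decay guess from the half-depth crossing right of the well.

    For a Morse well, E = -De/2 on the outer wall at a*(r - r_eq) =
    -ln(1 - sqrt(1/2)) ≈ 1.2279.
    """
    outer = (r > req0) & (e > -0.5 * de0)
    if np.any(outer):
        r_half = r[outer][0]
        if r_half > req0:
            return 1.2279471773885176 / (r_half - req0)
    return 2.0


def normalize_descriptor(series: DescriptorSeries) -> DescriptorSeries:
    """Min-max normalize a descriptor series onto [0, 1]."""
    if len(series.distances) < 3:
        raise ValueError("descriptor series needs at least 3 points")
    raw = series.raw_values
    lo, hi = float(raw.min()), float(raw.max())
    if hi - lo <= 0.0:
        raise ValueError(
            f"descriptor {series.name!r} is constant and cannot be normalized")
    return DescriptorSeries(series.name, series.distances, raw,
                            (raw - lo) / (hi - lo))


def fit_descriptor(series: DescriptorSeries) -> DescriptorFit:
    """Least-squares fit D0*exp(-k_desc*r) to a normalized descriptor series.

    The initial k_desc comes from a log-linear regression on values above
    1e-6; a non-decaying series (best k_desc <= 0) is rejected as unsuitable
    for cleavage detection.
    """
    if series.normalized_values is None:
        raise ValueError("descriptor must be normalized before fitting")
    r = series.distances
    v = series.normalized_values
    mask = v > 1e-6
    if mask.sum() < 2:
        raise FitError("too few positive descriptor values for a log-linear seed")
    slope, intercept = np.polyfit(r[mask], np.log(v[mask]), 1)
    if slope >= 0:
        raise FitError(
            f"descriptor {series.name!r} does not decay with distance; "
            "it is unsuitable for locating bond cleavage")
    p0 = [float(np.exp(intercept)), float(-slope)]

    def model(x, d0, k):
        return d0 * np.exp(-k * x)

    try:
        popt, _ = curve_fit(model, r, v, p0=p0,
                            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except RuntimeError as exc:
        raise FitError(f"descriptor fit did not converge: {exc}") from exc
    rss = float(np.sum((model(r, *popt) - v) ** 2))
    return DescriptorFit(float(popt[0]), float(popt[1]), rss)


def cleavage_distance(fit: DescriptorFit, gamma_cleave: float,
                      r_min: float | None = None) -> CleavagePoint:
    """Closed-form cleavage distance from the descriptor-slope cutoff.

    |dD_fit/dr| = k*D0*exp(-k*r) first reaches gamma_cleave at
    r_cleave = ln(k*D0/gamma_cleave)/k.  If ``r_min`` (scan start) is given
    and the slope is already below the cutoff there, the bond would be
    "broken" before the scan begins, which is rejected.
    """
    if gamma_cleave <= 0:
        raise ValueError("gamma_cleave must be positive")
    if r_min is not None and gamma_cleave >= fit.k_desc * fit.d0 * np.exp(
            -fit.k_desc * r_min):
        raise ValueError(
            "bond already broken at equilibrium: the descriptor slope is "
            f"below gamma_cleave={gamma_cleave} at the scan start r={r_min}")
    r_cleave = np.log(fit.k_desc * fit.d0 / gamma_cleave) / fit.k_desc
    return CleavagePoint(gamma_cleave=float(gamma_cleave), r_cleave=float(r_cleave))


def entropy_sigmoid(r, model: EntropySigmoid) -> np.ndarray:
    """Evaluate the sigmoid entropy contribution -T*dS_fit(r) in kJ/mol."""
    return model.predict(r)


# ---------------------------------------------------------------------------
# curve assembly and barrier search
# ---------------------------------------------------------------------------

def assemble_gibbs(morse: MorseFit, sigmoid: EntropySigmoid,
                   grid: np.ndarray) -> FreeEnergyResult:
    """Pointwise Gibbs curve dG(r) = dE_fit(r) + (-T dS_fit(r)) on ``grid``."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] > morse.r_eq + 1e-9:
        raise ValueError("grid must start at or before r_eq")
    return FreeEnergyResult(
        grid_r=grid,
        delta_g=morse.predict(grid) + sigmoid.predict(grid),
        morse=morse,
        sigmoid=sigmoid,
        k_sig_final=sigmoid.k_sig,
    )


def _evaluation_window(morse: MorseFit, sigmoid: EntropySigmoid,
                       r_end_hint: float | None) -> tuple[float, float]:
    """[r_eq, max(scan end, r_cleave + 10/k_sig)] — wide enough that both the
    Morse tail and the sigmoid are effectively saturated."""
    r_lo = morse.r_eq
    r_hi = sigmoid.r_cleave + 10.0 / sigmoid.k_sig
    if r_end_hint is not None:
        r_hi = max(r_hi, r_end_hint)
    return r_lo, max(r_hi, r_lo + 0.5)


def _fine_curve(morse, sigmoid, r_lo, r_hi, grid_step):
    n = max(int(np.ceil((r_hi - r_lo) / grid_step)) + 1, 16)
    r = np.linspace(r_lo, r_hi, n)
    return r, morse.predict(r) + sigmoid.predict(r)


def _parabolic_refine(r: np.ndarray, g: np.ndarray, i: int) -> float:
    """Three-point parabolic refinement of a grid maximum at index i; returns
    the refined abscissa (clamped to one grid step around r[i])."""
    if i <= 0 or i >= len(r) - 1:
        return float(r[i])
    y0, y1, y2 = g[i - 1], g[i], g[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not a concave triple
        return float(r[i])
    h = r[i] - r[i - 1]
    shift = 0.5 * h * (y0 - y2) / denom
    return float(r[i] + np.clip(shift, -h, h))


def find_barrier(result: FreeEnergyResult,
                 tol_barrier: float = TOL_BARRIER,
                 grid_step: float = GRID_STEP) -> FreeEnergyResult:
    """Locate the loose transition state and compute both barriers.

    The analytic curve is scanned at ``grid_step`` over the evaluation window
    and the global interior maximum beyond r_eq is refined parabolically.
    If that maximum exceeds neither the curve value at r_eq (dissociation
    reference) nor the infinite-separation asymptote (association reference)
    by more than ``tol_barrier``, the outcome is flagged no-barrier — a valid
    result for a purely downhill free-energy profile.
    """
    morse, sigmoid = result.morse, result.sigmoid
    r_lo, r_hi = _evaluation_window(morse, sigmoid, float(result.grid_r[-1]))
    r, g = _fine_curve(morse, sigmoid, r_lo, r_hi, grid_step)
    g_req = float(morse.predict(morse.r_eq) + sigmoid.predict(morse.r_eq))
    asymptote = sigmoid.amplitude

    i_max = int(np.argmax(g[1:-1])) + 1 if len(g) > 2 else 0
    interior_max = len(g) > 2 and g[i_max] >= g[0] and g[i_max] >= g[-1]
    out = replace(result)
    if not interior_max:
        out.no_barrier = True
        out.r_ts = None
        out.barrier_dissociation = None
        out.barrier_association = None
        return out

    r_ts = _parabolic_refine(r, g, i_max)
    g_ts = float(morse.predict(r_ts) + sigmoid.predict(r_ts))
    if g_ts < g[i_max]:  # refinement must never worsen the grid maximum
        r_ts, g_ts = float(r[i_max]), float(g[i_max])

    if g_ts - g_req <= tol_barrier and g_ts - asymptote <= tol_barrier:
        out.no_barrier = True
        out.r_ts = None
        out.barrier_dissociation = None
        out.barrier_association = None
        return out

    out.no_barrier = False
    out.r_ts = r_ts
    out.barrier_dissociation = g_ts - g_req
    out.barrier_association = g_ts - asymptote
    return out


def _post_ts_dip(r: np.ndarray, g: np.ndarray, r_ts: float,
                 tol_min: float) -> bool:
    """True if the curve has an interior local minimum beyond r_ts whose
    subsequent rise exceeds tol_min."""
    beyond = r > r_ts
    if beyond.sum() < 3:
        return False
    gb = g[beyond]
    # running maximum from the right: rise achievable after each point
    suffix_max = np.maximum.accumulate(gb[::-1])[::-1]
    rise = suffix_max - gb
    return bool(np.any(rise[:-1] > tol_min))


def tune_steepness(morse: MorseFit, amplitude: float, r_cleave: float,
                   k_start: float = K_START, shrink: float = K_SHRINK,
                   k_floor: float = K_FLOOR, tol_min: float = TOL_MIN,
                   tol_barrier: float = TOL_BARRIER,
                   grid_step: float = GRID_STEP,
                   r_end_hint: float | None = None,
                   ) -> tuple[EntropySigmoid, FreeEnergyResult]:
    """Find the largest sigmoid steepness giving no minimum after the TS.

    Starting from ``k_start`` the steepness is multiplied by ``shrink`` while
    the assembled free-energy curve still shows an interior local minimum
    beyond the transition state (deeper than ``tol_min``).  Returns the first
    accepted sigmoid together with its barrier analysis.  If no steepness
    yields a transition state at all, the no-barrier result at ``k_start`` is
    returned; hitting ``k_floor`` with the dip still present is an error.
    """
    if not (0 < shrink < 1):
        raise ValueError("shrink must be in (0, 1)")
    k = float(k_start)
    while True:
        sigmoid = EntropySigmoid(amplitude=amplitude, r_cleave=r_cleave, k_sig=k)
        r_lo, r_hi = _evaluation_window(morse, sigmoid, r_end_hint)
        grid = np.linspace(r_lo, r_hi, max(int((r_hi - r_lo) / 0.01) + 1, 16))
        result = find_barrier(assemble_gibbs(morse, sigmoid, grid),
                              tol_barrier=tol_barrier, grid_step=grid_step)
        if result.no_barrier:
            return sigmoid, result
        r, g = _fine_curve(morse, sigmoid, r_lo, r_hi, grid_step)
        if not _post_ts_dip(r, g, result.r_ts, tol_min):
            return sigmoid, result
        k *= shrink
        if k < k_floor:
            raise TuningError(
                f"steepness search reached the floor {k_floor} Å^-1 with a "
                "minimum still present after the transition state")


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(scan: DissociationScan, descriptor: DescriptorSeries,
                 amplitude: float, gamma_cleave: float,
                 temperature: float = 298.15,
                 direction: str = "dissociation",
                 fix_r_eq: float | None = None,
                 k_start: float = K_START, shrink: float = K_SHRINK,
                 k_floor: float = K_FLOOR, tol_min: float = TOL_MIN,
                 tol_barrier: float = TOL_BARRIER,
                 grid_step: float = GRID_STEP,
                 offset_at_req: bool = False) -> FreeEnergyResult:
    """Full barrier pipeline: Morse fit, descriptor fit, cleavage detection,
    steepness tuning and barrier extraction.

    ``amplitude`` is the dissociation entropy term -T*(S_A + S_B - S_AB) in
    kJ/mol (see :func:`barrierless.rrho.entropy_amplitude`).  The sigmoid is
    slightly nonzero at r_eq; by default that residual is kept (and reported
    in the metadata), with ``offset_at_req`` the reported curve is shifted so
    the entropy term is exactly zero at r_eq.  Both barriers are differences
    against references that shift along with the curve, so they are
    unaffected by the flag.  Each stage failure is re-raised as
    :class:`PipelineError` tagged with its stage.
    """
    if direction not in ("dissociation", "association"):
        raise ValueError(f"unknown direction: {direction!r}")
    try:
        morse = fit_morse(scan, fix_r_eq=fix_r_eq)
    except Exception as exc:
        raise PipelineError("fit_morse", exc) from exc
    try:
        normalized = normalize_descriptor(descriptor)
    except Exception as exc:
        raise PipelineError("normalize_descriptor", exc) from exc
    try:
        desc_fit = fit_descriptor(normalized)
    except Exception as exc:
        raise PipelineError("fit_descriptor", exc) from exc
    try:
        cleave = cleavage_distance(desc_fit, gamma_cleave,
                                   r_min=float(scan.distances[0]))
    except Exception as exc:
        raise PipelineError("cleavage_distance", exc) from exc
    try:
        sigmoid, result = tune_steepness(
            morse, amplitude, cleave.r_cleave,
            k_start=k_start, shrink=shrink, k_floor=k_floor,
            tol_min=tol_min, tol_barrier=tol_barrier, grid_step=grid_step,
            r_end_hint=float(scan.distances[-1]))
    except Exception as exc:
        raise PipelineError("tune_steepness", exc) from exc

    residual = float(sigmoid.predict(morse.r_eq))
    if offset_at_req:
        result.delta_g = result.delta_g - residual
    result.descriptor_fit = desc_fit
    result.cleavage = cleave
    result.metadata = {
        "gamma_cleave": gamma_cleave,
        "temperature": temperature,
        "direction": direction,
        "amplitude": amplitude,
        "descriptor_name": descriptor.name,
        "scan_label": scan.label,
        "sigmoid_residual_at_r_eq": residual,
        "offset_at_req": offset_at_req,
        "k_start": k_start,
        "shrink": shrink,
        "k_floor": k_floor,
        "tol_min": tol_min,
        "tol_barrier": tol_barrier,
    }
    return result
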
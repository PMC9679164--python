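"""Silent-substitution calibration of chromatic pairs.

A three-primary display drives four receptor classes (L, M, S, rod) through
the 4x3 excitation matrix ``M``, whose entry (r, c) is the excitation of
receptor r per unit *linear* drive of channel c:

    M[r, c] = sum_lambda SPD_c(lambda) * S_r(lambda) * dlambda * attenuation_c

Display non-linearity is an explicit per-channel gamma model; all silencing
algebra is carried out in linearized radiance space, so mis-specified gamma
shows up as residual contrast in the silenced class — exactly the failure
mode that `validate_pair` is designed to expose.

Two solvers are provided:

* cone-isolating pair — rods silenced, blue channel frozen, modulation
  confined to the one-dimensional rod-null direction of the red-green plane;
* rod-isolating pair — L and M cones silenced simultaneously, modulation
  along the 1-D null space of the (L, M) rows; the induced S-cone contrast is
  reported but deliberately unconstrained (three primaries cannot silence
  three classes).

Contrast between the two members of a pair is Michelson contrast per
receptor, |e_t - e_b| / (e_t + e_b).  In the default one-sided mode the
background is held fixed and the target modulates away from it, which makes
contrast a mildly non-linear function of the drive step (solved by bracketed
root-finding).  In bidirectional mode the pair straddles the background
symmetrically and contrast is exactly linear in the step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .spectra import RECEPTOR_NAMES, ReceptorSet, SpectralCurve

__all__ = [
    "DisplayModel",
    "ExcitationMatrix",
    "ChromaticPair",
    "build_excitation_matrix",
    "receptor_excitation",
    "michelson_contrast",
    "solve_cone_isolating_pair",
    "solve_rod_isolating_pair",
    "validate_pair",
]

CHANNEL_NAMES = ("R", "G", "B")


@dataclass(frozen=True)
class DisplayModel:
    """Three-primary display: SPDs at full drive, gamma, and attenuation.

    ``gamma`` holds one exponent per channel mapping drive voltage in [0, 1]
    to relative radiance (v -> v**gamma); ``attenuation`` is a scalar
    transmission factor per channel (fMRI mirror / neutral-density
    correction), each in (0, 1].
    """

    primaries: tuple
    gamma: np.ndarray = field(default_factory=lambda: np.ones(3))
    attenuation: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        if len(self.primaries) != 3:
            raise ValueError("need exactly three primaries (R, G, B)")
        g = np.broadcast_to(np.asarray(self.gamma, dtype=float), (3,)).copy()
        a = np.broadcast_to(np.asarray(self.attenuation, dtype=float), (3,)).copy()
        if np.any(g <= 0):
            raise ValueError("gamma exponents must be positive")
        if np.any(a <= 0) or np.any(a > 1):
            raise ValueError("attenuation must lie in (0, 1]")
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "attenuation", a)

    def linearize(self, drive: np.ndarray) -> np.ndarray:
        drive = np.asarray(drive, dtype=float)
        if np.any(drive < 0) or np.any(drive > 1):
            raise ValueError("drive values must lie in [0, 1]")
        return drive**self.gamma

    def delinearize(self, linear: np.ndarray) -> np.ndarray:
        linear = np.asarray(linear, dtype=float)
        if np.any(linear < -1e-12) or np.any(linear > 1 + 1e-12):
            raise ValueError("linear drive outside [0, 1] gamut")
        return np.clip(linear, 0.0, 1.0) ** (1.0 / self.gamma)


@dataclass(frozen=True)
class ExcitationMatrix:
    """4x3 receptor-by-channel excitation matrix (rows L, M, S, rod)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 3):
            raise ValueError("excitation matrix must be 4x3")
        if np.any(m < 0):
            raise ValueError("excitation entries must be non-negative")
        object.__setattr__(self, "matrix", m)

    def row(self, receptor: str) -> np.ndarray:
        return self.matrix[RECEPTOR_NAMES.index(receptor)]


def _common_grid(curves: list) -> np.ndarray:
    """Finest-step grid over the overlap of all curves' wavelength ranges."""
    lo = max(c.wavelength_nm[0] for c in curves)
    hi = min(c.wavelength_nm[-1] for c in curves)
    if hi <= lo:
        raise ValueError("spectra have non-overlapping wavelength ranges")
    step = min(c.step_nm for c in curves)
    n = int(round((hi - lo) / step)) + 1
    return np.linspace(lo, hi, n)


def build_excitation_matrix(
    display: DisplayModel, receptors: ReceptorSet
) -> ExcitationMatrix:
    """Riemann-sum excitation matrix from primary SPDs and sensitivities."""
    curves = list(display.primaries) + receptors.curves()
    grid = _common_grid(curves)
    dlam = grid[1] - grid[0]
    spd = np.stack([p.resample(grid).value for p in display.primaries])  # 3 x W
    sens = np.stack([c.resample(grid).value for c in receptors.curves()])  # 4 x W
    m = sens @ spd.T * dlam  # 4 x 3
    m *= display.attenuation[np.newaxis, :]
    return ExcitationMatrix(m)


def receptor_excitation(
    display: DisplayModel,
    receptors: ReceptorSet,
    drive: np.ndarray,
    matrix: ExcitationMatrix | None = None,
) -> np.ndarray:
    """Excitations (L, M, S, rod) for a gamma-corrected drive triplet."""
    if matrix is None:
        matrix = build_excitation_matrix(display, receptors)
    return matrix.matrix @ display.linearize(drive)


def michelson_contrast(e_target, e_background):
    """|e_t - e_b| / (e_t + e_b); elementwise over excitation vectors."""
    e_t = np.asarray(e_target, dtype=float)
    e_b = np.asarray(e_background, dtype=float)
    if np.any(e_t < 0) or np.any(e_b < 0):
        raise ValueError("excitations must be non-negative")
    denom = e_t + e_b
    if np.any(denom == 0):
        raise ValueError("undefined contrast: both excitations are zero")
    return np.abs(e_t - e_b) / denom


@dataclass(frozen=True)
class ChromaticPair:
    """Background/target drive settings and the receptor contrasts they induce."""

    background_drive: np.ndarray
    target_drive: np.ndarray
    receptor_contrasts: dict

    def __post_init__(self) -> None:
        b = np.asarray(self.background_drive, dtype=float)
        t = np.asarray(self.target_drive, dtype=float)
        for d in (b, t):
            if d.shape != (3,) or np.any(d < 0) or np.any(d > 1):
                raise ValueError("drives must be 3-vectors in [0, 1]")
        object.__setattr__(self, "background_drive", b)
        object.__setattr__(self, "target_drive", t)

    def recompute_contrasts(
        self,
        display: DisplayModel,
        receptors: ReceptorSet,
        matrix: ExcitationMatrix | None = None,
    ) -> dict:
        e_b = receptor_excitation(display, receptors, self.background_drive, matrix)
        e_t = receptor_excitation(display, receptors, self.target_drive, matrix)
        c = michelson_contrast(e_t, e_b)
        return dict(zip(RECEPTOR_NAMES, c))


def _pair_from_linear(
    display: DisplayModel,
    receptors: ReceptorSet,
    matrix: ExcitationMatrix,
    lin_bg: np.ndarray,
    lin_target: np.ndarray,
) -> ChromaticPair:
    bg = display.delinearize(lin_bg)
    tg = display.delinearize(lin_target)
    pair = ChromaticPair(bg, tg, {})
    contrasts = pair.recompute_contrasts(display, receptors, matrix)
    return ChromaticPair(bg, tg, contrasts)


def _gamut_scale_limit(lin_bg: np.ndarray, direction: np.ndarray) -> tuple:
    """Largest step along ``direction`` keeping linear drive in [0, 1].

    Returns (limit, limiting_channel_name).
    """
    limit = np.inf
    channel = None
    for c in range(3):
        d = direction[c]
        if d > 0:
            bound = (1.0 - lin_bg[c]) / d
        elif d < 0:
            bound = -lin_bg[c] / d
        else:
            continue
        if bound < limit:
            limit = bound
            channel = CHANNEL_NAMES[c]
    return limit, channel


def _solve_scale(
    matrix: ExcitationMatrix,
    lin_bg: np.ndarray,
    direction: np.ndarray,
    target_contrast: float,
    contrast_rows: list,
    bidirectional: bool,
) -> tuple:
    """Find the step size alpha achieving the requested mean contrast.

    ``contrast_rows`` indexes the receptor rows whose Michelson contrasts are
    averaged (L and M for the cone pair; rod for the rod pair).  Returns the
    linearized (background, target) pair of drive vectors.
    """
    m = matrix.matrix
    e_bg = m @ lin_bg
    g = m @ direction
    rows = np.asarray(contrast_rows)
    if np.any(e_bg[rows] <= 0):
        raise ValueError("background excitation is zero for a targeted receptor")

    if bidirectional:
        # members at lin_bg +/- alpha/2 * direction: contrast is linear in alpha
        rate = float(np.mean(np.abs(g[rows]) / (2.0 * e_bg[rows])))
        if rate <= 0:
            raise ValueError("degenerate direction: no contrast in targeted receptors")
        alpha = target_contrast / rate
        lim_up, ch_up = _gamut_scale_limit(lin_bg, direction)
        lim_dn, ch_dn = _gamut_scale_limit(lin_bg, -direction)
        lim = min(lim_up, lim_dn)
        if alpha / 2.0 > lim:
            ch = ch_up if lim_up <= lim_dn else ch_dn
            raise ValueError(
                f"requested contrast {target_contrast} exceeds the display gamut; "
                f"limiting channel: {ch}"
            )
        return lin_bg - 0.5 * alpha * direction, lin_bg + 0.5 * alpha * direction

    lim, channel = _gamut_scale_limit(lin_bg, direction)
    if not np.isfinite(lim):
        raise ValueError("degenerate direction: no drive change possible")

    def mean_contrast(alpha: float) -> float:
        e_t = e_bg + alpha * g
        return float(np.mean(np.abs(alpha * g[rows]) / (e_t[rows] + e_bg[rows])))

    if target_contrast == 0:
        return lin_bg, lin_bg.copy()
    achievable = mean_contrast(lim)
    if achievable < target_contrast:
        raise ValueError(
            f"requested contrast {target_contrast} exceeds the display gamut "
            f"(max {achievable:.4f}); limiting channel: {channel}"
        )
    alpha = brentq(
        lambda a: mean_contrast(a) - target_contrast,
        0.0,
        lim,
        xtol=1e-15,
        rtol=8.9e-16,
        maxiter=200,
    )
    return lin_bg, lin_bg + alpha * direction


def solve_cone_isolating_pair(
    display: DisplayModel,
    receptors: ReceptorSet,
    background_drive: np.ndarray,
    target_lm_contrast: float,
    bidirectional: bool = False,
    matrix: ExcitationMatrix | None = None,
) -> ChromaticPair:
    """Rod-silent chromatic pair with the requested mean L/M Michelson contrast.

    The blue channel is held fixed and the modulation follows the
    one-dimensional rod-null direction of the linearized red-green plane,
    which shifts the stimulus toward long wavelengths where rod sensitivity
    (and hence calibration error) is low.
    """
    if target_lm_contrast < 0:
        raise ValueError("target contrast must be non-negative")
    if matrix is None:
        matrix = build_excitation_matrix(display, receptors)
    rod = matrix.row("rod")
    # rod-null direction in the (R, G) plane: rod . (dR, dG) = 0
    direction = np.array([rod[1], -rod[0], 0.0])
    norm = np.hypot(rod[0], rod[1])
    if norm == 0:
        raise ValueError("degenerate rod-null direction in the red-green plane")
    direction /= norm
    lm = matrix.matrix[:2, :2]
    if np.max(np.abs(lm @ direction[:2])) < 1e-12 * (np.max(np.abs(lm)) + 1e-300):
        # rod row proportional to both cone rows in the R-G plane
        raise ValueError("degenerate rod-null direction: L and M are also silenced")
    # orient toward an L+M increment for a well-defined sign convention
    g = matrix.matrix @ direction
    if g[0] + g[1] < 0:
        direction = -direction
    lin_bg = display.linearize(np.asarray(background_drive, dtype=float))
    lin_b, lin_t = _solve_scale(
        matrix, lin_bg, direction, target_lm_contrast, [0, 1], bidirectional
    )
    return _pair_from_linear(display, receptors, matrix, lin_b, lin_t)


def solve_rod_isolating_pair(
    display: DisplayModel,
    receptors: ReceptorSet,
    background_drive: np.ndarray,
    target_rod_contrast: float,
    bidirectional: bool = False,
    matrix: ExcitationMatrix | None = None,
) -> ChromaticPair:
    """L/M-silent chromatic pair with the requested rod Michelson contrast.

    Modulation follows the 1-D null space of the L and M rows; the S-cone
    contrast this induces is reported in ``receptor_contrasts`` but is not
    constrained (with three primaries only two classes can be silenced).
    """
    if target_rod_contrast < 0:
        raise ValueError("target contrast must be non-negative")
    if matrix is None:
        matrix = build_excitation_matrix(display, receptors)
    l_row, m_row = matrix.row("L"), matrix.row("M")
    direction = np.cross(l_row, m_row)
    norm = np.linalg.norm(direction)
    if norm < 1e-12 * (np.linalg.norm(l_row) * np.linalg.norm(m_row) + 1e-300):
        raise ValueError("empty null space: L and M rows are proportional")
    direction /= norm
    g = matrix.matrix @ direction
    if g[3] < 0:  # orient toward a rod increment
        direction = -direction
    lin_bg = display.linearize(np.asarray(background_drive, dtype=float))
    lin_b, lin_t = _solve_scale(
        matrix, lin_bg, direction, target_rod_contrast, [3], bidirectional
    )
    return _pair_from_linear(display, receptors, matrix, lin_b, lin_t)


def validate_pair(
    pair: ChromaticPair,
    display: DisplayModel,
    receptors: ReceptorSet,
    silenced: list,
    tol: float = 1e-6,
) -> dict:
    """Residual contrast per silenced receptor and a pass/fail verdict.

    Run against a *different* display model than the one used to solve (for
    example with perturbed SPDs or a mis-specified gamma) this quantifies how
    much the silenced class leaks through under calibration error.
    """
    contrasts = pair.recompute_contrasts(display, receptors)
    residuals = {r: contrasts[r] for r in silenced}
    return {
        "residuals": residuals,
        "contrasts": contrasts,
        "tol": tol,
        "passed": all(v <= tol for v in residuals.values()),
    }
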
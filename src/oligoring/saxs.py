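"""Small-angle X-ray scattering: Debye curves and Guinier R_g extraction.

The momentum transfer is s = 4π sinθ / λ (nm⁻¹). In the Guinier regime
(s·R_g ≲ 1.3) the intensity of a monodisperse solution follows

    I(s) = I(0) · exp(-s² R_g² / 3),

so ln I is linear in s² with slope -R_g²/3. The admissible window depends
on the very R_g being estimated; the fit therefore iterates window
selection and regression to a fixed point, the convention of standard
SAXS reduction tools. Model intensities for bead models come from the
Debye formula, I(s) = Σ_i Σ_j f_i f_j sinc(s·r_ij).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "GuinierResult",
    "ScatteringCurve",
    "debye_intensity",
    "guinier_fit",
    "read_dat",
    "write_dat",
]


@dataclass
class ScatteringCurve:
    """I(s) on a strictly increasing s grid (s in nm⁻¹)."""

    s: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.s.shape != self.intensity.shape or self.s.ndim != 1:
            raise ValueError("s and intensity must be 1-d arrays of equal length")
        if self.sigma is not None and self.sigma.shape != self.s.shape:
            raise ValueError("sigma must match the s grid length")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("s grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.s)


def read_dat(path: str | Path) -> ScatteringCurve:
    """Read a 3-column (s, I, sigma) or 2-column DAT curve.

    Whitespace- or comma-separated; free-text header/footer lines are
    skipped, the common layout of reduced SAXS data files.
    """
    rows: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        tokens = line.replace(",", " ").split()
        if len(tokens) < 2:
            continue
        try:
            values = [float(t) for t in tokens[:3]]
        except ValueError:
            continue
        rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no numeric data rows")
    n_cols = min(len(r) for r in rows)
    data = np.array([r[:n_cols] for r in rows])
    sigma = data[:, 2] if n_cols >= 3 else None
    return ScatteringCurve(s=data[:, 0], intensity=data[:, 1], sigma=sigma)


def write_dat(curve: ScatteringCurve, path: str | Path, header: str = "") -> None:
    lines = [f"# {header}"] if header else []
    lines.append("# s[1/nm]  I(s)" + ("  sigma" if curve.sigma is not None else ""))
    for i in range(len(curve)):
        row = f"{curve.s[i]:.6e}  {curve.intensity[i]:.6e}"
        if curve.sigma is not None:
            row += f"  {curve.sigma[i]:.6e}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def debye_intensity(
    coords: np.ndarray,
    s_grid: np.ndarray,
    weights: np.ndarray | None = None,
    coords_in_nm: bool = False,
) -> ScatteringCurve:
    """Debye-formula intensity of a bead model on an s grid (nm⁻¹).

    Coordinates are Å by package convention (set ``coords_in_nm`` for nm
    inputs); ``weights`` are per-bead form factors, default 1. I(0) equals
    (Σf)² and the double sum is symmetric in bead order.
    """
    coords = np.asarray(coords, dtype=float)
    s_grid = np.asarray(s_grid, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("need at least one bead")
    if np.any(s_grid < 0):
        raise ValueError("s values must be non-negative")
    if weights is None:
        weights = np.ones(len(coords))
    weights = np.asarray(weights, dtype=float)

    total = float(weights.sum())
    if len(coords) == 1:
        return ScatteringCurve(s=s_grid, intensity=np.full_like(s_grid, total**2))

    r = pdist(coords)
    if not coords_in_nm:
        r = r / 10.0  # Å → nm, so s·r is dimensionless
    wpair = _pairwise_products(weights)  # same pair order as pdist
    diag = float(np.sum(weights**2))

    intensity = np.empty(len(s_grid))
    for i, s in enumerate(s_grid):
        x = s * r
        intensity[i] = diag + 2.0 * float(np.sum(wpair * np.sinc(x / np.pi)))
    return ScatteringCurve(s=s_grid, intensity=intensity)


def _pairwise_products(w: np.ndarray) -> np.ndarray:
    """Upper-triangle products w_i w_j in the same order as scipy's pdist."""
    n = len(w)
    iu, ju = np.triu_indices(n, k=1)
    return w[iu] * w[ju]


@dataclass
class GuinierResult:
    """Outcome of an iterative Guinier fit."""

    rg: float                  # nm
    rg_stderr: float           # nm
    i0: float                  # extrapolated zero-angle intensity
    window: tuple[float, float]  # [s_min, s_max] actually used, nm⁻¹
    s_rg_max: float            # s_max · rg, dimensionless
    r_squared: float
    n_points: int
    converged: bool

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rg_nm": self.rg,
            "rg_stderr_nm": self.rg_stderr,
            "i0": self.i0,
            "window_nm_inv": list(self.window),
            "s_rg_max": self.s_rg_max,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "converged": self.converged,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _wls_line(x: np.ndarray, y: np.ndarray, sigma_y: np.ndarray | None):
    """Weighted least-squares line fit; returns slope, intercept, slope stderr, R²."""
    w = np.ones_like(x) if sigma_y is None else 1.0 / sigma_y**2
    sw, sx, sy = w.sum(), (w * x).sum(), (w * y).sum()
    sxx, sxy = (w * x * x).sum(), (w * x * y).sum()
    delta = sw * sxx - sx**2
    slope = (sw * sxy - sx * sy) / delta
    intercept = (sxx * sy - sx * sxy) / delta
    resid = y - (slope * x + intercept)
    if sigma_y is None:
        dof = max(len(x) - 2, 1)
        var_slope = (resid**2).sum() / dof * sw / delta
    else:
        var_slope = sw / delta
    ybar = sy / sw
    ss_tot = (w * (y - ybar) ** 2).sum()
    r2 = 1.0 - (w * resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, float(np.sqrt(var_slope)), float(r2)


def guinier_fit(
    curve: ScatteringCurve,
    s_rg_limit: float = 1.3,
    s_min: float | None = None,
    max_iter: int = 20,
) -> GuinierResult:
    """Fit the Guinier law with iterative window selection.

    Starting from a small low-angle window above ``s_min``, ln I is
    regressed on s² (1/σ²-weighted when uncertainties are present), the
    implied R_g sets a new window ceiling s_max = s_rg_limit / R_g, and
    the fit repeats until the window is a fixed point. An oscillating
    window is reported with ``converged=False`` rather than raised.
    """
    lo = float(curve.s[0]) if s_min is None else float(s_min)
    mask_base = curve.s >= lo
    if mask_base.sum() < 3:
        raise ValueError("fewer than 3 points above s_min")

    idx_base = np.where(mask_base)[0]
    # initial window: the lower half of the admissible range, wide enough
    # that the first slope estimate is not noise-dominated
    current = idx_base[: max(3, len(idx_base) // 2)]
    seen: list[tuple[int, ...]] = []
    converged = False

    slope = intercept = slope_err = r2 = 0.0
    for _ in range(max_iter):
        s_w = curve.s[current]
        i_w = curve.intensity[current]
        if np.any(i_w <= 0):
            raise ValueError("non-positive intensity inside the Guinier window")
        sigma_ln = None if curve.sigma is None else curve.sigma[current] / i_w
        slope, intercept, slope_err, r2 = _wls_line(s_w**2, np.log(i_w), sigma_ln)
        if slope >= 0:
            raise ValueError("non-negative Guinier slope: curve has no decaying low-angle regime")
        rg = float(np.sqrt(-3.0 * slope))
        s_max = s_rg_limit / rg
        new = idx_base[(curve.s[idx_base] <= s_max)]
        if len(new) < 3:
            new = idx_base[:3]
        key = tuple(new)
        if key == tuple(current):
            converged = True
            break
        if key in seen:
            current = new  # oscillation: keep the latest window, flag it
            s_w = curve.s[current]
            i_w = curve.intensity[current]
            sigma_ln = None if curve.sigma is None else curve.sigma[current] / i_w
            slope, intercept, slope_err, r2 = _wls_line(s_w**2, np.log(i_w), sigma_ln)
            break
        seen.append(tuple(current))
        current = new

    rg = float(np.sqrt(-3.0 * slope))
    rg_stderr = 3.0 * slope_err / (2.0 * rg)
    s_used = curve.s[current]
    return GuinierResult(
        rg=rg,
        rg_stderr=float(rg_stderr),
        i0=float(np.exp(intercept)),
        window=(float(s_used[0]), float(s_used[-1])),
        s_rg_max=float(s_used[-1] * rg),
        r_squared=r2,
        n_points=len(current),
        converged=converged,
    )
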
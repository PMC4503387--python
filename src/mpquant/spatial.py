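"""Spatial patterning statistics on circular colonies.

Quantifies how cells organise radially on a confined circular pattern:
per-annulus cell densities (the "cell density heatmap"), marker-positive
fractions (e.g. OCT4+, EdU+), the nucleus shape index, the perimeter/centre
spatial density ratio, and a two-term power fit of marker intensity versus
colony thickness.

Nuclei enter as a table (pandas DataFrame) with centroids in μm relative to
the pattern centre, nucleus axes, and boolean marker columns — the schema
produced by :mod:`mpquant.synthetic` and documented in FORMATS.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import InsufficientDataError
from .tracks import CENTRE, PERIMETER, RegionRule

NUCLEI_REQUIRED = ["x_um", "y_um"]


@dataclass(frozen=True)
class PatternGeometry:
    """Circular pattern: centre (μm), diameter (μm), annulus width (μm).

    The default 15-μm annulus width matches the resolution at which density
    heatmaps resolve the perimeter condensation band; diameters of
    200/400/600 μm are the usual pattern sizes.
    """

    centre: tuple[float, float] = (0.0, 0.0)
    diameter: float = 400.0
    annulus_width: float = 15.0

    def __post_init__(self):
        if not self.diameter > 0:
            raise ValueError("diameter must be positive")
        if not 0 < self.annulus_width <= self.radius:
            raise ValueError("annulus_width must be in (0, radius]")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def n_annuli(self) -> int:
        return int(math.ceil(self.radius / self.annulus_width - 1e-9))

    def annulus_edges(self) -> np.ndarray:
        """Inner/outer radii; the outermost annulus is truncated at the radius."""
        edges = np.arange(self.n_annuli + 1) * self.annulus_width
        edges[-1] = self.radius
        return edges


@dataclass
class DensityMap:
    """Per-annulus cell counts and densities.

    ``table`` columns: annulus, inner_r, outer_r, cell_count, area_um2,
    density (cells/μm²).  ``n_outside`` tallies nuclei whose centroid fell
    outside the pattern circle (excluded from every annulus), so that
    Σ cell_count + n_outside equals the input nucleus count.
    """

    table: pd.DataFrame
    n_outside: int
    geometry: PatternGeometry

    @property
    def total_inside(self) -> int:
        return int(self.table.cell_count.sum())


def _radii(nuclei: pd.DataFrame, geom: PatternGeometry) -> np.ndarray:
    return np.hypot(nuclei["x_um"].to_numpy() - geom.centre[0],
                    nuclei["y_um"].to_numpy() - geom.centre[1])


def annulus_density_map(nuclei: pd.DataFrame, geom: PatternGeometry) -> DensityMap:
    """Assign nuclei to concentric annuli and compute densities.

    Annuli are half-open ``[j·w, (j+1)·w)`` from the centre outward; the
    terminal annulus is truncated at the pattern radius and closed there, so
    a nucleus exactly on the rim still counts.  Nuclei beyond the radius are
    excluded and reported in ``n_outside``.
    """
    if len(nuclei) == 0:
        raise InsufficientDataError("empty nuclei table")
    r = _radii(nuclei, geom)
    R, w = geom.radius, geom.annulus_width
    outside = r > R + 1e-9
    idx = np.minimum(np.floor(r / w).astype(int), geom.n_annuli - 1)
    counts = np.bincount(idx[~outside], minlength=geom.n_annuli)
    edges = geom.annulus_edges()
    areas = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    table = pd.DataFrame({
        "annulus": np.arange(geom.n_annuli),
        "inner_r": edges[:-1],
        "outer_r": edges[1:],
        "cell_count": counts,
        "area_um2": areas,
        "density": counts / areas,
    })
    return DensityMap(table=table, n_outside=int(outside.sum()), geometry=geom)


def marker_positive_fraction(nuclei: pd.DataFrame, marker: str,
                             geom: PatternGeometry | None = None,
                             by_region: bool = False,
                             region_rule: RegionRule | None = None):
    """Fraction of marker-positive nuclei, overall or per centre/perimeter.

    The fraction is positive count / total count from the boolean ``marker``
    column (the ratio of marker-stained to DAPI nuclei counts).  With
    ``by_region`` the same region rule as the migration analysis partitions
    nuclei by centroid radius; returns a dict with ``overall``, ``centre``
    and ``perimeter`` entries (NaN for an empty region).
    """
    if marker not in nuclei.columns:
        raise KeyError(f"marker column {marker!r} not present")
    if len(nuclei) == 0:
        raise InsufficientDataError("cannot compute a fraction of zero nuclei")
    flags = nuclei[marker].astype(bool).to_numpy()
    overall = float(flags.mean())
    if not by_region:
        return overall
    rule = region_rule or RegionRule(
        centre=geom.centre if geom is not None else (0.0, 0.0)
    )
    r = np.hypot(nuclei["x_um"].to_numpy() - rule.centre[0],
                 nuclei["y_um"].to_numpy() - rule.centre[1])
    perim = r > rule.radial_threshold
    out = {"overall": overall}
    for name, mask in ((CENTRE, ~perim), (PERIMETER, perim)):
        out[name] = float(flags[mask].mean()) if mask.any() else float("nan")
    return out


def nucleus_shape_index(nuclei: pd.DataFrame,
                        region_rule: RegionRule | None = None,
                        geom: PatternGeometry | None = None):
    """Nucleus shape index: longest axis divided by shortest axis (≥ 1).

    Returns ``(per_nucleus, summary, rejected)``: a Series of indices
    aligned with the accepted rows, a per-region mean ± s.d. table when a
    region rule is given (else overall), and a DataFrame of rejected records
    with reasons (non-positive axes).
    """
    major = nuclei["major_um"].to_numpy(dtype=float)
    minor = nuclei["minor_um"].to_numpy(dtype=float)
    bad = ~((major > 0) & (minor > 0))
    rejected = nuclei.loc[bad].copy()
    rejected["reason"] = "non-positive axis"
    ok = nuclei.loc[~bad]
    long_ax = np.maximum(major[~bad], minor[~bad])
    short_ax = np.minimum(major[~bad], minor[~bad])
    index = pd.Series(long_ax / short_ax, index=ok.index, name="shape_index")
    rule = region_rule or RegionRule()
    geom = geom or PatternGeometry()
    r = np.hypot(ok["x_um"].to_numpy() - rule.centre[0],
                 ok["y_um"].to_numpy() - rule.centre[1])
    region = np.where(r > rule.radial_threshold, PERIMETER, CENTRE)
    rows = []
    for name in (CENTRE, PERIMETER):
        vals = index.to_numpy()[region == name]
        rows.append({
            "region": name, "n": len(vals),
            "mean": float(vals.mean()) if len(vals) else float("nan"),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        })
    summary = pd.DataFrame(rows).set_index("region")
    return index, summary, rejected


def spatial_density_ratio(density_map: DensityMap,
                          region_rule: RegionRule | None = None) -> float:
    """Pooled perimeter density divided by pooled centre density.

    Annuli are split at the region rule's radial threshold (an annulus
    straddling the threshold goes to the side containing its midpoint);
    each side's density pools counts over pooled area.  A ratio above 1
    indicates condensation at the perimeter.  An empty perimeter gives 0; a
    zero centre density gives ``inf`` (flag, not an exception).
    """
    rule = region_rule or RegionRule()
    t = density_map.table
    mid = (t.inner_r + t.outer_r) / 2.0
    perim = mid.to_numpy() > rule.radial_threshold
    if perim.all():
        raise ValueError("region rule leaves no centre annulus")
    if not perim.any():
        raise ValueError("region rule leaves no perimeter annulus")
    area_c = t.area_um2[~perim].sum()
    area_p = t.area_um2[perim].sum()
    dens_c = t.cell_count[~perim].sum() / area_c
    dens_p = t.cell_count[perim].sum() / area_p
    if dens_p == 0.0:
        return 0.0
    if dens_c == 0.0:
        return float("inf")
    return float(dens_p / dens_c)


# ---------------------------------------------------------------------------
# two-term power profile fit
# ---------------------------------------------------------------------------

def _power(x, a, b, c):
    return a * np.power(x, b) + c


class PowerProfileModel:
    """Two-term power model y = a·x^b + c of intensity versus thickness.

    ``y`` is the marker intensity divided by the normaliser channel (e.g.
    OCT4 or E-cadherin over DAPI); ``x`` is the colony thickness.  Fitted by
    nonlinear least squares from several exponent starting points.
    """

    def __init__(self, thickness, intensity, normalizer=None):
        x = np.asarray(thickness, dtype=float)
        y = np.asarray(intensity, dtype=float)
        if normalizer is not None:
            nz = np.asarray(normalizer, dtype=float)
            if nz.shape != y.shape:
                raise ValueError("normalizer must match intensity in length")
            if np.any(nz == 0):
                raise ValueError("normalizer contains zeros")
            y = y / nz
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("thickness and intensity must be 1-D of equal length")
        if len(x) < 4:
            raise InsufficientDataError("need at least 4 points for a 3-parameter fit")
        if np.any(x <= 0):
            raise ValueError("thickness values must be positive")
        self.x = x
        self.y = y

    def fit(self) -> "PowerProfileResults":
        x, y = self.x, self.y
        sst = float(((y - y.mean()) ** 2).sum())
        if sst <= 1e-30 * max(1.0, float(np.abs(y).max()) ** 2):
            # constant profile: a ~ 0 with b unidentifiable
            return PowerProfileResults(
                model=self, a=0.0, b=0.0, c=float(y.mean()), sse=0.0,
                cov=np.full((3, 3), np.nan), converged=True, unidentifiable=True,
            )
        best = None
        span = float(y.max() - y.min())
        for b0 in (0.5, 1.0, 2.0, -0.5, -1.0):
            p0 = (span / max(x.max() ** b0 - x.min() ** b0, 1e-9), b0, float(y.min()))
            try:
                popt, pcov = optimize.curve_fit(
                    _power, x, y, p0=p0, maxfev=20000, ftol=1e-14, xtol=1e-14,
                )
            except Exception:
                continue
            sse = float(((y - _power(x, *popt)) ** 2).sum())
            if best is None or sse < best[0]:
                best = (sse, popt, pcov)
        if best is None:
            return PowerProfileResults(
                model=self, a=np.nan, b=np.nan, c=np.nan, sse=np.nan,
                cov=np.full((3, 3), np.nan), converged=False, unidentifiable=False,
            )
        sse, popt, pcov = best
        res = PowerProfileResults(
            model=self, a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
            sse=sse, cov=pcov, converged=True, unidentifiable=False,
        )
        ci = res.conf_int()
        if not np.all(np.isfinite(pcov)) or (ci[1, 0] < 0 < ci[1, 1] and abs(res.b) > 1e-8):
            res.unidentifiable = True
        return res


@dataclass
class PowerProfileResults:
    """Coefficients and fit quality of the two-term power fit.

    Reports the coefficients with 95% confidence intervals and the fitting
    statistics SSE, RMSE (√(SSE/(n−3))) and R².
    """

    model: PowerProfileModel
    a: float
    b: float
    c: float
    sse: float
    cov: np.ndarray
    converged: bool
    unidentifiable: bool

    @property
    def nobs(self) -> int:
        return len(self.model.x)

    @property
    def dof(self) -> int:
        return max(self.nobs - 3, 1)

    @property
    def rmse(self) -> float:
        return math.sqrt(self.sse / self.dof)

    @property
    def rsquared(self) -> float:
        y = self.model.y
        sst = float(((y - y.mean()) ** 2).sum())
        # a numerically constant profile has no variance to explain
        if sst <= 1e-24 * max(1.0, float(np.abs(y).max()) ** 2):
            return 0.0
        return 1.0 - self.sse / sst

    def predict(self, x) -> np.ndarray:
        return _power(np.asarray(x, dtype=float), self.a, self.b, self.c)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Rows (a, b, c) of t-based confidence bounds."""
        se = np.sqrt(np.diag(self.cov))
        tval = stats.t.ppf(1 - alpha / 2, self.dof)
        centre = np.array([self.a, self.b, self.c])
        return np.column_stack([centre - tval * se, centre + tval * se])

    def to_dict(self) -> dict:
        ci = self.conf_int()
        return {
            "a": self.a, "b": self.b, "c": self.c,
            "ci95": {k: [float(ci[i, 0]), float(ci[i, 1])]
                     for i, k in enumerate("abc")},
            "sse": self.sse, "rmse": self.rmse, "rsquared": self.rsquared,
            "converged": self.converged, "unidentifiable": self.unidentifiable,
        }

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Two-term power fit  y = a*x^b + c",
            "=" * 44,
            f"n points:       {self.nobs}",
            f"converged:      {self.converged}",
            f"unidentifiable: {self.unidentifiable}",
        ]
        for i, k in enumerate("abc"):
            v = getattr(self, k)
            lines.append(f"{k} = {v:.6g}   95% CI [{ci[i, 0]:.6g}, {ci[i, 1]:.6g}]")
        lines += [
            f"SSE  = {self.sse:.6g}",
            f"RMSE = {self.rmse:.6g}",
            f"R^2  = {self.rsquared:.6g}",
        ]
        return "\n".join(lines)


def fit_power_profile(thickness, intensity, normalizer=None) -> PowerProfileResults:
    """Convenience wrapper around :class:`PowerProfileModel`."""
    return PowerProfileModel(thickness, intensity, normalizer).fit()


def plot_density_map(density_map: DensityMap, path):
    """Render the annulus density profile as a radial heatmap PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = density_map.table
    R = density_map.geometry.radius
    n = 200
    ax_grid = np.linspace(-R, R, n)
    xx, yy = np.meshgrid(ax_grid, ax_grid)
    r = np.hypot(xx, yy)
    img = np.full_like(r, np.nan)
    for _, row in t.iterrows():
        mask = (r >= row.inner_r) & (r < row.outer_r if row.outer_r < R else r <= R)
        img[mask] = row.density
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(img, extent=[-R, R, -R, R], cmap="inferno", origin="lower")
    fig.colorbar(im, ax=ax, label="density (cells/um^2)")
    ax.set_title("Cell density heatmap")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
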
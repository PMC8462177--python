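"""Synthetic landscapes, occurrences, trails and demography with known truth.

Everything here is a pure function of (truth, seed): the same
:class:`SyntheticTruth` and seed reproduce every dataset bit-for-bit.

The landscape is a spectral-synthesis Gaussian random field: a rugged
elevation surface, winter temperature declining with elevation at a fixed
lapse rate, and summer precipitation increasing with elevation, each with
small independent field noise. The true probability-of-occurrence surface
is logistic in standardized TRI (+), winter temperature (-) and summer
precipitation (+), favoring rugged, cold, wet terrain. Demography tables
emulate the field protocol: square-meter plots nested in sites, counts from
a log-linear Poisson process with site/plot intercepts and observation-level
overdispersion, masses cube-root normal, covers drawn as Braun-Blanquet
ranks, trail distances measured against a synthetic trail network.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import demography, geodata
from .geodata import GridSpec, Raster, TrailSet

__all__ = [
    "SyntheticTruth",
    "make_landscape",
    "true_occupancy",
    "sample_occurrences",
    "make_trails",
    "make_demography",
]


@dataclass
class SyntheticTruth:
    # landscape
    n_rows: int = 60
    n_cols: int = 60
    cell_size: float = 1000.0            # map units (m); ~1 km cells
    elev_min: float = 200.0
    elev_max: float = 2500.0
    spectral_exponent: float = 3.0       # power-law slope of the elevation field
    lapse_rate: float = 6.5e-3           # deg C lost per m of elevation
    temp_base: float = 12.0              # winter temperature at elevation 0
    temp_noise_sd: float = 0.3
    precip_base: float = 120.0           # summer precipitation (mm) at elevation 0
    precip_per_m: float = 0.12
    precip_noise_sd: float = 15.0
    substrate_keep_frac: float = 0.7     # fraction of cells on suitable bedrock
    landcover_keep_frac: float = 0.85
    # future scenario deltas (warming pushes the range upslope)
    future_temp_delta: float = 2.8
    future_precip_factor: float = 1.05
    # true occupancy: logistic in standardized (tri, temp, precip); sharp
    # coefficients make suitable habitat a rare joint tail (rugged + cold +
    # wet), as for a true alpine specialist
    occ_intercept: float = -17.0
    occ_beta_tri: float = 5.0
    occ_beta_temp: float = -4.5
    occ_beta_precip: float = 1.5
    # demography: fixed effects on the standardized scale (signs follow the
    # fitted seed-production models: Env +, Trail +, hemiparasites +, woody -)
    count_intercept: float = 6.0         # exp(6) ~ 400 seeds per m^2
    beta_env: float = 0.5
    beta_trail: float = 0.5
    beta_hemi: float = 0.45
    beta_woody: float = -0.45
    beta_height: float = 0.2
    beta_cushion: float = 0.0            # truly null covariate
    beta_env_trail: float = 0.0          # interaction absent from the truth
    sd_site: float = 0.25
    sd_plot: float = 0.25                # plot-level OLRE of the count model
    mass_intercept: float = 4.5          # cube-root mg per m^2 scale
    gamma_env: float = 0.5
    gamma_trail: float = 0.45
    gamma_hemi: float = 0.4
    gamma_woody: float = -0.4
    gamma_height: float = 0.15
    mass_sd_site: float = 0.25
    mass_resid_sd: float = 0.7
    # inflorescence-level processes (height enters per inflorescence)
    infl_count_intercept: float = 4.5    # exp(4.5) ~ 90 seeds per inflorescence
    infl_sd_plot: float = 0.2
    infl_sd_olre: float = 0.25
    infl_mass_intercept: float = 2.3     # cube-root mg per inflorescence
    infl_mass_resid_sd: float = 0.3
    mean_inflorescences: float = 5.0     # n_infl ~ 1 + Poisson(mean - 1)
    mean_anthodia: float = 8.0
    seed: int = 0

    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, 0.0, self.n_rows * self.cell_size, self.cell_size)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# random fields


def _gaussian_field(rng: np.random.Generator, shape: tuple[int, int], exponent: float) -> np.ndarray:
    """Spectral synthesis: white noise shaped by a k^(-exponent/2) amplitude."""
    white = rng.standard_normal(shape)
    spec = np.fft.fft2(white)
    ky = np.fft.fftfreq(shape[0])[:, None]
    kx = np.fft.fftfreq(shape[1])[None, :]
    k = np.sqrt(kx**2 + ky**2)
    k[0, 0] = np.inf  # kill the DC component
    amp = k ** (-exponent / 2.0)
    fieldv = np.real(np.fft.ifft2(spec * amp))
    fieldv -= fieldv.mean()
    sd = fieldv.std()
    return fieldv / sd if sd > 0 else fieldv


def make_landscape(truth: SyntheticTruth, seed: int | None = None) -> dict[str, Raster]:
    """Elevation, winter temperature, summer precipitation, TRI and masks,
    for both the present day and the future scenario."""
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    spec = truth.grid()
    shape = spec.shape

    base = _gaussian_field(rng, shape, truth.spectral_exponent)
    lo, hi = base.min(), base.max()
    span = hi - lo if hi > lo else 1.0
    elev = truth.elev_min + (base - lo) / span * (truth.elev_max - truth.elev_min)
    elevation = Raster(spec, elev, "elevation")

    t_noise = _gaussian_field(rng, shape, truth.spectral_exponent) * truth.temp_noise_sd
    temp = truth.temp_base - truth.lapse_rate * elev + t_noise
    p_noise = _gaussian_field(rng, shape, truth.spectral_exponent) * truth.precip_noise_sd
    precip = np.maximum(truth.precip_base + truth.precip_per_m * elev + p_noise, 0.0)

    tri = geodata.compute_tri(elevation)

    blob = _gaussian_field(rng, shape, truth.spectral_exponent + 1.0)
    substrate = (blob > np.quantile(blob, 1.0 - truth.substrate_keep_frac)).astype(float)
    blob2 = _gaussian_field(rng, shape, truth.spectral_exponent + 1.0)
    landcover = (blob2 > np.quantile(blob2, 1.0 - truth.landcover_keep_frac)).astype(float)

    return {
        "elevation": elevation,
        "temperature": Raster(spec, temp, "temperature"),
        "precipitation": Raster(spec, precip, "precipitation"),
        "tri": tri,
        "substrate_mask": Raster(spec, substrate, "substrate_mask"),
        "landcover_mask": Raster(spec, landcover, "landcover_mask"),
        "temperature_future": Raster(spec, temp + truth.future_temp_delta, "temperature"),
        "precipitation_future": Raster(
            spec, precip * truth.future_precip_factor, "precipitation"
        ),
    }


def _standardize(values: np.ndarray, ref: np.ndarray) -> np.ndarray:
    m, s = np.nanmean(ref), np.nanstd(ref)
    return (values - m) / (s if s > 0 else 1.0)


def true_occupancy(truth: SyntheticTruth, rasters: dict[str, Raster], scenario: str = "current") -> Raster:
    """The generative probability-of-occurrence surface P*.

    Environmental fields are standardized against the *present-day* domain so
    current and future surfaces share one scale.
    """
    tri = rasters["tri"].values
    temp_ref = rasters["temperature"].values
    precip_ref = rasters["precipitation"].values
    temp = rasters["temperature_future"].values if scenario == "future" else temp_ref
    precip = rasters["precipitation_future"].values if scenario == "future" else precip_ref
    eta = (
        truth.occ_intercept
        + truth.occ_beta_tri * _standardize(tri, tri)
        + truth.occ_beta_temp * _standardize(temp, temp_ref)
        + truth.occ_beta_precip * _standardize(precip, precip_ref)
    )
    p = expit(eta)
    return Raster(rasters["tri"].spec, p, "p_true")


def sample_occurrences(
    truth: SyntheticTruth,
    rasters: dict[str, Raster],
    n_points: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Presence points sampled cell-wise proportional to P*, with coordinate
    jitter inside the cell; duplicate cells are allowed (they exercise the
    deduplication step)."""
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    p_star = true_occupancy(truth, rasters)
    spec = p_star.spec
    p = np.nan_to_num(p_star.values, nan=0.0).ravel()
    total = p.sum()
    if total == 0 or n_points == 0:
        return pd.DataFrame(columns=["x", "y", "label"])
    flat = rng.choice(p.size, size=n_points, replace=True, p=p / total)
    rows, cols = np.unravel_index(flat, spec.shape)
    jitter_x = rng.uniform(0.05, 0.95, n_points)
    jitter_y = rng.uniform(0.05, 0.95, n_points)
    x = spec.x_origin + (cols + jitter_x) * spec.cell_size
    y = spec.y_origin - (rows + jitter_y) * spec.cell_size
    return pd.DataFrame({"x": x, "y": y, "label": "presence"})


def make_trails(
    truth: SyntheticTruth,
    rasters: dict[str, Raster],
    n_trails: int = 12,
    steps: int = 40,
    seed: int | None = None,
) -> TrailSet:
    """Random-walk polylines biased toward low-TRI terrain (valley paths)."""
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    spec = rasters["tri"].spec
    tri = np.nan_to_num(rasters["tri"].values, nan=np.inf)
    xmin, ymin, xmax, ymax = spec.extent
    lines = []
    for _ in range(n_trails):
        r = rng.integers(1, spec.n_rows - 1)
        c = rng.integers(1, spec.n_cols - 1)
        verts = []
        for _s in range(steps):
            x, y = spec.cell_center(r, c)
            verts.append((float(x), float(y)))
            # candidate moves: 8 neighbours; prefer smooth (low TRI) cells
            cand = [
                (r + dr, c + dc)
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if not (dr == 0 and dc == 0)
                and 0 <= r + dr < spec.n_rows
                and 0 <= c + dc < spec.n_cols
            ]
            weights = np.array([1.0 / (1.0 + tri[rr, cc]) for rr, cc in cand])
            weights = weights / weights.sum()
            r, c = cand[rng.choice(len(cand), p=weights)]
        arr = np.asarray(verts)
        arr[:, 0] = np.clip(arr[:, 0], xmin, xmax)
        arr[:, 1] = np.clip(arr[:, 1], ymin, ymax)
        if len(np.unique(arr, axis=0)) >= 2:
            lines.append(arr)
    return TrailSet(lines)


# ---------------------------------------------------------------------------
# demography


def _draw_bb_rank(rng: np.random.Generator, p_zero: float) -> str:
    if rng.random() < p_zero:
        return "0"
    return rng.choice(["+", "1", "2", "3"], p=[0.4, 0.3, 0.2, 0.1])


def make_demography(
    truth: SyntheticTruth,
    favorability: Raster,
    trails: TrailSet,
    n_sites: int = 7,
    plots_per_site: int = 7,
    seed: int | None = None,
    noise: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate plots.csv / inflorescences.csv style tables.

    Plots cluster around high-favorability cells within sites. The
    plot-level responses are generated directly from the log-linear Poisson
    (counts) and cube-root-normal (mass) processes on the standardized
    design; inflorescence records are generated from the matching
    inflorescence-level processes sharing the plot design plus a
    per-inflorescence height term. In ``noise=False`` mode all random
    effects and noise are zero, inflorescence number is fixed, and counts
    are rounded expectations, so fits recover the truth almost exactly.

    Returns (plots, inflorescences, truth_info) where ``truth_info`` records
    the standardized-scale design actually used (for recovery tests).
    """
    if n_sites < 2 or plots_per_site < 2:
        raise ValueError("need at least 2 sites and 2 plots per site")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    spec = favorability.spec
    n_plots = n_sites * plots_per_site

    # site centers at high-favorability cells
    fav_vals = np.nan_to_num(favorability.values, nan=0.0)
    flat_idx = np.argsort(fav_vals.ravel())[::-1][: max(n_sites * 10, 50)]
    centers = rng.choice(flat_idx, size=n_sites, replace=False)
    c_rows, c_cols = np.unravel_index(centers, spec.shape)

    rows_ = []
    for s in range(n_sites):
        for p in range(plots_per_site):
            r = int(np.clip(c_rows[s] + rng.integers(-2, 3), 0, spec.n_rows - 1))
            c = int(np.clip(c_cols[s] + rng.integers(-2, 3), 0, spec.n_cols - 1))
            x, y = spec.cell_center(r, c)
            # jitter off the cell center so trail distances vary within cells
            x += rng.uniform(-0.3, 0.3) * spec.cell_size
            y += rng.uniform(-0.3, 0.3) * spec.cell_size
            rows_.append((f"site{s}", f"site{s}_plot{p}", float(x), float(y), r, c))
    plots = pd.DataFrame(rows_, columns=["site_id", "plot_id", "x", "y", "row", "col"])
    plots["favorability"] = np.clip(
        fav_vals[plots["row"], plots["col"]], 1e-4, 1 - 1e-4
    )
    plots["trail_distance_m"] = geodata.distance_to_trails(plots, trails)

    covers_h, covers_c, covers_w, ranks = [], [], [], []
    for _ in range(n_plots):
        rh = _draw_bb_rank(rng, 0.35)
        rc = _draw_bb_rank(rng, 0.5)
        rw = _draw_bb_rank(rng, 0.3)
        ranks.append((rh, rc, rw))
        covers_h.append(demography.braun_blanquet_to_cover(rh))
        covers_c.append(demography.braun_blanquet_to_cover(rc))
        covers_w.append(demography.braun_blanquet_to_cover(rw))
    plots["hemiparasite_cover"] = covers_h
    plots["cushion_cover"] = covers_c
    plots["woody_cover"] = covers_w
    plots["mean_inflorescence_height_cm"] = np.round(rng.normal(15.0, 3.0, n_plots), 1)
    if noise:
        plots["n_inflorescences"] = 1 + rng.poisson(truth.mean_inflorescences - 1.0, n_plots)
    else:
        plots["n_inflorescences"] = int(round(truth.mean_inflorescences))

    # standardized design shared by both levels
    predictors = [
        "favorability",
        "trail_distance_m",
        "hemiparasite_cover",
        "cushion_cover",
        "woody_cover",
        "mean_inflorescence_height_cm",
    ]
    std, scaling = demography.prepare_predictors(plots, predictors)
    z_env = std["favorability"].to_numpy()
    z_trail = std["trail_distance_m"].to_numpy()
    z_hemi = std["hemiparasite_cover"].to_numpy()
    z_cush = std["cushion_cover"].to_numpy()
    z_woody = std["woody_cover"].to_numpy()
    z_height = std["mean_inflorescence_height_cm"].to_numpy()

    site_codes = pd.factorize(plots["site_id"])[0]
    u_site = rng.normal(0.0, truth.sd_site, n_sites) if noise else np.zeros(n_sites)
    e_plot = rng.normal(0.0, truth.sd_plot, n_plots) if noise else np.zeros(n_plots)

    eta_fixed = (
        truth.count_intercept
        + truth.beta_env * z_env
        + truth.beta_trail * z_trail
        + truth.beta_hemi * z_hemi
        + truth.beta_cushion * z_cush
        + truth.beta_woody * z_woody
        + truth.beta_height * z_height
        + truth.beta_env_trail * z_env * z_trail
    )
    eta = eta_fixed + u_site[site_codes] + e_plot
    mu = np.exp(eta)
    plots["seed_number_per_m2"] = rng.poisson(mu) if noise else np.round(mu).astype(int)

    u_site_m = rng.normal(0.0, truth.mass_sd_site, n_sites) if noise else np.zeros(n_sites)
    eps_m = rng.normal(0.0, truth.mass_resid_sd, n_plots) if noise else np.zeros(n_plots)
    cbrt_mass = (
        truth.mass_intercept
        + truth.gamma_env * z_env
        + truth.gamma_trail * z_trail
        + truth.gamma_hemi * z_hemi
        + truth.gamma_woody * z_woody
        + truth.gamma_height * z_height
        + u_site_m[site_codes]
        + eps_m
    )
    plots["dry_seed_mass_mg_per_m2"] = np.maximum(cbrt_mass, 0.0) ** 3

    # inflorescence tables: 3 sampled inflorescences per plot
    infl_rows = []
    u_site_i = rng.normal(0.0, truth.sd_site, n_sites) if noise else np.zeros(n_sites)
    v_plot_i = rng.normal(0.0, truth.infl_sd_plot, n_plots) if noise else np.zeros(n_plots)
    u_site_im = rng.normal(0.0, truth.mass_sd_site, n_sites) if noise else np.zeros(n_sites)
    v_plot_im = rng.normal(0.0, truth.infl_sd_plot, n_plots) if noise else np.zeros(n_plots)
    h_sd = float(np.std(plots["mean_inflorescence_height_cm"], ddof=1))
    h_mean = float(np.mean(plots["mean_inflorescence_height_cm"]))
    for i in range(n_plots):
        for j in range(3):
            height = plots["mean_inflorescence_height_cm"].iat[i] + (
                rng.normal(0.0, 1.5) if noise else 0.0
            )
            zh = (height - h_mean) / h_sd
            eta_ij = (
                truth.infl_count_intercept
                + truth.beta_env * z_env[i] * 0.66
                + truth.beta_trail * z_trail[i] * 0.5
                + truth.beta_hemi * z_hemi[i]
                + truth.beta_woody * z_woody[i]
                + truth.beta_height * zh
                + u_site_i[site_codes[i]]
                + v_plot_i[i]
                + (rng.normal(0.0, truth.infl_sd_olre) if noise else 0.0)
            )
            y_ij = int(rng.poisson(np.exp(eta_ij))) if noise else int(round(np.exp(eta_ij)))
            cbrt_m_ij = (
                truth.infl_mass_intercept
                + truth.gamma_env * z_env[i] * 0.5
                + truth.gamma_trail * z_trail[i] * 0.42
                + truth.gamma_hemi * z_hemi[i] * 0.85
                + truth.gamma_woody * z_woody[i] * 0.95
                + truth.gamma_height * zh
                + u_site_im[site_codes[i]]
                + v_plot_im[i]
                + (rng.normal(0.0, truth.infl_mass_resid_sd) if noise else 0.0)
            )
            dry_mass = max(cbrt_m_ij, 0.0) ** 3
            anthodia = (
                1 + int(rng.poisson(truth.mean_anthodia - 1.0))
                if noise
                else int(round(truth.mean_anthodia))
            )
            infl_rows.append(
                {
                    "site_id": plots["site_id"].iat[i],
                    "plot_id": plots["plot_id"].iat[i],
                    "inflorescence_id": f"{plots['plot_id'].iat[i]}_infl{j}",
                    "height_cm": round(float(height), 1),
                    "anthodium_count": anthodia,
                    "mean_seeds_per_anthodium": y_ij / anthodia,
                    "mean_fresh_mass_per_anthodium_mg": dry_mass
                    / demography.FRESH_TO_DRY_COEF
                    / anthodia,
                }
            )
    infl = pd.DataFrame(infl_rows)

    truth_info = {
        "design": std,
        "scaling": scaling,
        "site_codes": site_codes,
        "count_beta": {
            "(Intercept)": truth.count_intercept,
            "favorability": truth.beta_env,
            "trail_distance_m": truth.beta_trail,
            "hemiparasite_cover": truth.beta_hemi,
            "cushion_cover": truth.beta_cushion,
            "woody_cover": truth.beta_woody,
            "mean_inflorescence_height_cm": truth.beta_height,
            "favorability:trail_distance_m": truth.beta_env_trail,
        },
        "mass_gamma": {
            "(Intercept)": truth.mass_intercept,
            "favorability": truth.gamma_env,
            "trail_distance_m": truth.gamma_trail,
            "hemiparasite_cover": truth.gamma_hemi,
            "woody_cover": truth.gamma_woody,
            "mean_inflorescence_height_cm": truth.gamma_height,
        },
    }
    return plots.drop(columns=["row", "col"]), infl, truth_info
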
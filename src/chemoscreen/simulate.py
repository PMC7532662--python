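"""Synthetic ground-truth generators for every pipeline stage.

Each generator is deterministic given its seed and returns its ground
truth alongside the data, so every analysis stage can be validated by
recovery against a known answer with no external data:

* ``simulate_screen_plate`` — triplicate CCK-8 viability plates under a
  multiplicative siRNA x drug model with lognormal noise; the true
  per-target sensitization index follows in closed form from the
  noiseless effects.
* ``simulate_dose_response`` — 4PL viability readouts at a 6-dose
  design with additive Gaussian noise.
* ``simulate_filament_image`` — curvilinear filaments (persistent
  random walks, Gaussian cross-section ~1 px) inside an elliptical
  cell, with Poisson + Gaussian noise; the rasterized filament mask is
  the polymerized-area oracle.
* ``simulate_comet_movie`` — Gaussian spots moving at per-track
  constant speeds with slight angular diffusion.
* ``simulate_contingency`` — two-group categorical tables with a
  specified log-odds association.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "simulate_screen_plate",
    "simulate_dose_response",
    "simulate_filament_image",
    "simulate_comet_movie",
    "simulate_contingency",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# screen plates


def simulate_screen_plate(
    n_genes: int = 30,
    duplexes_per_gene: int = 3,
    true_si: dict | None = None,
    knockdown_effect: float = 0.9,
    drug_effect: float = 0.5,
    noise_cv: float = 0.02,
    n_replicates: int = 3,
    n_control_wells: int = 3,
    baseline_od: float = 1.0,
    seed=0,
):
    """Simulate a long-format screen plate with known per-target SI.

    The noiseless well model is multiplicative:
    ``od = baseline * knockdown * drug * interaction``; for a target
    with programmed sensitization index ``s`` the interaction factor is
    ``g = 1 - s / (knockdown * drug)``, which makes the closed-form SI
    of the noiseless plate exactly ``s``.  Multiplicative lognormal
    noise with coefficient of variation ``noise_cv`` (typical CCK-8
    replicate scatter ~2%) is applied per well.

    ``true_si`` maps gene name -> programmed SI (genes default to
    ``gene01..``; unlisted genes get SI 0).  Returns
    ``(plate DataFrame, truth DataFrame)`` with the truth holding the
    per-target programmed SI.
    """
    rng = _rng(seed)
    genes = [f"gene{i + 1:02d}" for i in range(n_genes)]
    true_si = dict(true_si or {})
    unknown = set(true_si) - set(genes)
    if unknown:
        raise ValueError(f"true_si refers to unknown genes: {sorted(unknown)}")
    if not 0 < drug_effect <= 1 or not 0 < knockdown_effect <= 1.5:
        raise ValueError("effects must be positive viability fractions")

    sigma = np.sqrt(np.log1p(noise_cv**2))  # lognormal with unit mean, CV=noise_cv

    def noisy(mean_od: float) -> float:
        if noise_cv == 0:
            return mean_od
        return float(mean_od * rng.lognormal(-sigma**2 / 2, sigma))

    rows, truth = [], []
    for rep in range(1, n_replicates + 1):
        for w in range(n_control_wells):
            rows.append(("NT_control" if w == 0 else f"NT_control_w{w}", "nontargeting",
                         True, "vehicle", rep, noisy(baseline_od)))
            rows.append(("NT_control" if w == 0 else f"NT_control_w{w}", "nontargeting",
                         True, "drug", rep, noisy(baseline_od * drug_effect)))
    for gene in genes:
        s = float(true_si.get(gene, 0.0))
        g = 1.0 - s / (knockdown_effect * drug_effect)
        if g <= 0:
            raise ValueError(f"programmed SI {s} for {gene} too large for the effect sizes")
        for d in range(1, duplexes_per_gene + 1):
            tid = f"{gene}_si{d}"
            truth.append({"target_id": tid, "gene": gene, "true_si": s})
            for rep in range(1, n_replicates + 1):
                rows.append((tid, gene, False, "vehicle", rep,
                             noisy(baseline_od * knockdown_effect)))
                rows.append((tid, gene, False, "drug", rep,
                             noisy(baseline_od * knockdown_effect * drug_effect * g)))
    plate = pd.DataFrame(
        rows, columns=["target_id", "gene", "is_control", "condition", "replicate", "od"]
    )
    return plate, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# dose-response


def simulate_dose_response(
    ic50: float = 10.0,
    hill: float = 1.0,
    top: float = 1.0,
    bottom: float = 0.0,
    doses=None,
    n_replicates: int = 3,
    noise_sd: float = 0.05,
    noise_model: str = "multiplicative",
    include_vehicle: bool = True,
    seed=0,
) -> pd.DataFrame:
    """Simulate 4PL viability readouts; doses default to a 6-point log series.

    Noise is multiplicative lognormal with coefficient of variation
    ``noise_sd`` by default — viability readouts scatter in proportion
    to their signal, the same noise family as the screen-plate
    generator — or additive Gaussian with ``noise_model="additive"``.

    Returns a DataFrame (concentration, response, replicate) whose
    ground truth is the 4PL closed form at the given parameters.
    Raises for a degenerate design (fewer than 2 distinct doses).
    """
    from .dose_response import four_pl

    rng = _rng(seed)
    if doses is None:
        doses = ic50 * np.logspace(-2, 2, 6)  # 6 concentrations bracketing the IC50
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0 (vehicle is added separately)")
    if len(np.unique(doses)) < 2:
        raise ValueError("invalid design: doses must include at least 2 distinct values")
    if noise_model not in ("multiplicative", "additive"):
        raise ValueError("noise_model must be 'multiplicative' or 'additive'")

    sigma = np.sqrt(np.log1p(noise_sd**2))

    def add_noise(clean):
        clean = np.atleast_1d(np.asarray(clean, dtype=float))
        if noise_sd == 0:
            return clean
        if noise_model == "multiplicative":
            return clean * rng.lognormal(-sigma**2 / 2, sigma, size=clean.shape)
        return clean + rng.normal(0, noise_sd, size=clean.shape)

    rows = []
    for rep in range(1, n_replicates + 1):
        if include_vehicle:
            rows.append((0.0, float(add_noise(top)[0]), rep))
        clean = four_pl(doses, bottom, top, np.log10(ic50), hill)
        for d, r in zip(doses, add_noise(clean)):
            rows.append((float(d), float(r), rep))
    return pd.DataFrame(rows, columns=["concentration", "response", "replicate"])


# ---------------------------------------------------------------------------
# filament images


def _ellipse_mask(shape, semi_axes) -> np.ndarray:
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ay, ax = semi_axes
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def simulate_filament_image(
    shape=(256, 256),
    n_filaments: int | None = 40,
    target_fraction: float | None = None,
    filament_intensity: float = 60.0,
    background: float = 10.0,
    psf_sigma: float = 1.0,
    cell_axes=None,
    turn_sd_rad: float = 0.25,
    step_px: float = 1.0,
    gaussian_noise_sd: float = 2.0,
    seed=0,
):
    """Render curvilinear filaments inside an elliptical cell.

    Filaments are persistent random walks (heading diffuses with SD
    ``turn_sd_rad`` per px step) started at random in-cell positions and
    rasterized with a Gaussian cross-section of SD ``psf_sigma``
    (~1 px, diffraction-limited microtubule width).  Photon noise is
    Poisson on the clean image plus additive Gaussian read noise.

    If ``target_fraction`` (percent) is given, filaments are added until
    the rasterized in-cell structure mask reaches that coverage.

    Returns ``(image, cell_mask, structure_mask, true_fraction_percent)``
    — the rasterized structure mask is the area oracle.
    """
    rng = _rng(seed)
    ny, nx = shape
    if cell_axes is None:
        cell_axes = (0.42 * ny, 0.45 * nx)
    cell = _ellipse_mask(shape, cell_axes)
    density = np.zeros(shape, dtype=float)
    footprint = np.zeros(shape, dtype=bool)

    def add_filament():
        in_cell = np.argwhere(cell)
        y, x = in_cell[rng.integers(len(in_cell))].astype(float)
        theta = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.15, 0.6) * min(ny, nx)
        n_steps = int(length / step_px)
        for _ in range(n_steps):
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < ny and 0 <= ix < nx):
                break
            density[iy, ix] += 1.0
            footprint[iy, ix] = True
            theta += rng.normal(0, turn_sd_rad)
            y += step_px * np.sin(theta)
            x += step_px * np.cos(theta)

    if target_fraction is not None:
        max_filaments = 10000
        count = 0
        while count < max_filaments:
            add_filament()
            count += 1
            frac = 100.0 * np.count_nonzero(
                ndimage.binary_dilation(footprint) & cell
            ) / np.count_nonzero(cell)
            if frac >= target_fraction:
                break
    else:
        for _ in range(int(n_filaments)):
            add_filament()

    structure = ndimage.binary_dilation(footprint) & cell  # ~2 px wide rasterized filaments
    true_fraction = 100.0 * np.count_nonzero(structure) / np.count_nonzero(cell)

    clean = background + filament_intensity * ndimage.gaussian_filter(density, psf_sigma)
    clean *= cell  # dark outside the cell
    clean += 0.2 * background  # faint coverslip background everywhere
    image = rng.poisson(np.clip(clean, 0, None)).astype(float)
    if gaussian_noise_sd:
        image += rng.normal(0, gaussian_noise_sd, size=shape)
    return image, cell, structure, float(true_fraction)


# ---------------------------------------------------------------------------
# comet movies


def simulate_comet_movie(
    n_comets: int = 30,
    speed_mean: float = 10.0,
    speed_sd: float = 1.0,
    pixel_size_um: float = 0.065,
    frame_interval_s: float = 2.0,
    n_frames: int = 15,
    shape=(128, 128),
    spot_sigma: float = 1.5,
    snr: float = 10.0,
    background: float = 10.0,
    noise_sd: float = 2.0,
    turn_sd_rad: float = 0.05,
    seed=0,
):
    """Simulate an EB1-comet time-lapse with known per-track speeds.

    Comets nucleate at random in-frame positions and headings, move at a
    per-track constant speed drawn from N(speed_mean, speed_sd) µm/min
    with small angular diffusion per frame, and are rendered as Gaussian
    spots of amplitude ``snr * noise_sd`` over a flat background with
    additive Gaussian noise.  The default geometry matches a 2 s / 15
    frame (~30 s) acquisition at 0.065 µm/px.

    Returns ``(frames ndarray [n_frames, ny, nx], truth DataFrame)``
    with truth columns (track_id, frame, x, y, speed_um_min).
    """
    rng = _rng(seed)
    ny, nx = shape
    amp = snr * noise_sd
    margin = 4 * spot_sigma
    speeds = np.clip(rng.normal(speed_mean, speed_sd, n_comets), 0.1, None)
    # µm/min -> px/frame
    px_per_frame = speeds / 60.0 * frame_interval_s / pixel_size_um
    xs = rng.uniform(margin, nx - margin, n_comets)
    ys = rng.uniform(margin, ny - margin, n_comets)
    thetas = rng.uniform(0, 2 * np.pi, n_comets)

    frames = np.zeros((n_frames, ny, nx), dtype=float)
    truth_rows = []
    yy, xx = np.mgrid[0:ny, 0:nx]
    pos = np.stack([xs, ys], axis=1)
    for f in range(n_frames):
        clean = np.full((ny, nx), background, dtype=float)
        for i in range(n_comets):
            x, y = pos[i]
            if 0 <= x < nx and 0 <= y < ny:
                clean += amp * np.exp(
                    -((xx - x) ** 2 + (yy - y) ** 2) / (2 * spot_sigma**2)
                )
                truth_rows.append(
                    {"track_id": i, "frame": f, "x": float(x), "y": float(y),
                     "speed_um_min": float(speeds[i])}
                )
        frames[f] = clean + rng.normal(0, noise_sd, size=(ny, nx))
        thetas += rng.normal(0, turn_sd_rad, n_comets)
        pos[:, 0] += px_per_frame * np.cos(thetas)
        pos[:, 1] += px_per_frame * np.sin(thetas)
    return frames, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# contingency tables


def simulate_contingency(
    n_per_group=(150, 80),
    base_probs=(0.6, 0.4),
    effect: float = 0.0,
    level_labels=None,
    group_labels=("low", "high"),
    seed=0,
) -> pd.DataFrame:
    """Simulate a two-group labeled contingency table with known association.

    Group 1 draws its level from ``base_probs``; group 2 from the same
    probabilities with ``effect`` added to the log-odds of the LAST
    level (softmax renormalized).  ``effect = 0`` is the exact null.
    Returns a levels x groups DataFrame of counts.
    """
    rng = _rng(seed)
    p = np.asarray(base_probs, dtype=float)
    if np.any(p <= 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("base_probs must be positive and sum to 1")
    logits = np.log(p)
    logits2 = logits.copy()
    logits2[-1] += effect
    p2 = np.exp(logits2 - logits2.max())
    p2 /= p2.sum()
    k = len(p)
    if level_labels is None:
        level_labels = [f"level{i + 1}" for i in range(k)]
    c1 = rng.multinomial(n_per_group[0], p)
    c2 = rng.multinomial(n_per_group[1], p2)
    return pd.DataFrame({group_labels[0]: c1, group_labels[1]: c2}, index=list(level_labels))
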
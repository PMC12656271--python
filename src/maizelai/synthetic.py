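"""Synthetic five-band maize-canopy imagery with known leaf area index.

The generator emulates a density × nitrogen field trial observed by a
five-band (B/G/R/RE/NIR) multispectral camera over several acquisition
dates.  Radiometry follows a two-endmember mixture: each plot image is a
soil background partially covered by leaf "clumps" (disc stamps), with the
soil-visible fraction tied to LAI through the Beer–Lambert gap fraction

    g(LAI) = exp(-k_ext * LAI).

LAI itself follows a unimodal seasonal trajectory scaled by planting
density and nitrogen rate, with the D3N2 treatment attaining the seasonal
maximum.  Per-date illumination gain, per-blob shading, per-sample leaf
spectrum jitter, per-plot soil brightness jitter and per-pixel noise add
the radiometric variability that real acquisitions carry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

BAND_NAMES = ("B", "G", "R", "RE", "NIR")
#: band centres in nm, for reference only
BAND_WAVELENGTHS_NM = {"B": 450, "G": 560, "R": 650, "RE": 730, "NIR": 840}

DEFAULT_DENSITIES = ("D1", "D2", "D3")  # 42k / 63k / 84k plants ha-1
DEFAULT_N_RATES = ("N0", "N1", "N2", "N3")  # 0 / 80 / 160 / 240 kg N ha-1

#: configured LAI range (m2 m-2) every generated sample is clipped to
LAI_RANGE = (0.77, 5.28)

# Seasonal position of each acquisition date in [0, 1]; the main scenario
# observes five dates, the independent scenario four (the fourth date of
# the main campaign is missing there).
MAIN_DATE_POSITIONS = (0.30, 0.45, 0.55, 0.72, 0.85)
INDEPENDENT_DATE_POSITIONS = (0.30, 0.45, 0.55, 0.85)

# Treatment multipliers on expected LAI: monotone in density, and in N up
# to N2 with a slight decline at N3 (over-fertilisation plateau), so the
# expected seasonal maximum sits at D3N2.
DENSITY_FACTORS = {"D1": 0.75, "D2": 0.90, "D3": 1.00}
NITROGEN_FACTORS = {"N0": 0.70, "N1": 0.85, "N2": 1.00, "N3": 0.95}

_PEAK_POSITION = 0.72  # seasonal position of maximum LAI (early grain filling)
_CURVE_SHAPE = 2.0
_PEAK_LAI = 5.1  # expected LAI of D3N2 at the seasonal peak
_PLOT_NOISE_SD = 0.08  # lognormal sigma of per-plot-date LAI noise


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout of the simulated trial."""

    densities: tuple[str, ...] = DEFAULT_DENSITIES
    n_rates: tuple[str, ...] = DEFAULT_N_RATES
    replicates: int = 3
    dates: int = 5
    image_size: int = 128
    seed: int = 0

    @property
    def n_plots(self) -> int:
        return len(self.densities) * len(self.n_rates) * self.replicates

    @property
    def n_samples(self) -> int:
        return self.n_plots * self.dates


@dataclass(frozen=True)
class CanopyModel:
    """Radiometric model of one plot scene.

    ``k_ext`` is the Beer–Lambert extinction coefficient; ``leaf_spectrum``
    and ``soil_spectrum`` are endmember reflectances for (B, G, R, RE, NIR).
    ``shading_sd``, ``leaf_jitter_sd`` and ``soil_jitter_sd`` are lognormal
    sigmas of, respectively, per-blob shading, per-sample leaf-spectrum
    jitter and per-plot soil-brightness jitter.
    """

    k_ext: float = 0.6
    leaf_spectrum: tuple[float, ...] = (0.05, 0.12, 0.06, 0.35, 0.50)
    soil_spectrum: tuple[float, ...] = (0.12, 0.18, 0.22, 0.26, 0.30)
    blob_radius_px: float = 3.0
    noise_sd: float = 0.01
    illumination_gain: float = 1.0
    shading_sd: float = 0.15
    leaf_jitter_sd: float = 0.05
    soil_jitter_sd: float = 0.08
    gain_range: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self):
        if not 0.0 < self.k_ext <= 2.0:
            raise ValueError(f"k_ext must be in (0, 2], got {self.k_ext}")
        for name in ("leaf_spectrum", "soil_spectrum"):
            spec = getattr(self, name)
            if len(spec) != len(BAND_NAMES):
                raise ValueError(f"{name} must have {len(BAND_NAMES)} entries")
            if np.any(np.asarray(spec) < 0) or np.any(np.asarray(spec) > 1):
                raise ValueError(f"{name} values must lie in [0, 1]")


@dataclass
class BandStack:
    """Five co-registered reflectance bands for one plot-date."""

    bands: dict[str, np.ndarray]

    def __post_init__(self):
        if set(self.bands) != set(BAND_NAMES):
            raise ValueError(f"band names must be exactly {set(BAND_NAMES)}")
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError("all bands must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands[BAND_NAMES[0]].shape

    def as_array(self) -> np.ndarray:
        """(5, H, W) array in canonical band order."""
        return np.stack([self.bands[b] for b in BAND_NAMES])


@dataclass(frozen=True)
class SampleRecord:
    plot_id: str
    density_label: str
    nitrogen_label: str
    replicate: int
    date_index: int
    lai_true: float
    scenario: str = "main"

    def __post_init__(self):
        if self.lai_true <= 0:
            raise ValueError("lai_true must be positive")


class ConfigurationError(ValueError):
    """Unknown treatment label or inconsistent design."""


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic keyed child generator of a root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _season_curve(x: float) -> float:
    """Unimodal canopy development curve, 1.0 at the seasonal peak."""
    p, a = _PEAK_POSITION, _CURVE_SHAPE
    if not 0.0 < x < 1.0:
        return 0.0
    return (x / p) ** a * ((1.0 - x) / (1.0 - p)) ** (a * (1.0 - p) / p)


def lai_expected(
    density_label: str,
    nitrogen_label: str,
    date_index: int,
    date_positions: tuple[float, ...] = MAIN_DATE_POSITIONS,
) -> float:
    """Noise-free expected LAI for one treatment and date (clipped to range)."""
    if density_label not in DENSITY_FACTORS:
        raise ConfigurationError(f"unknown density label {density_label!r}")
    if nitrogen_label not in NITROGEN_FACTORS:
        raise ConfigurationError(f"unknown nitrogen label {nitrogen_label!r}")
    if not 1 <= date_index <= len(date_positions):
        raise ConfigurationError(
            f"date_index {date_index} outside 1..{len(date_positions)}"
        )
    value = (
        _PEAK_LAI
        * DENSITY_FACTORS[density_label]
        * NITROGEN_FACTORS[nitrogen_label]
        * _season_curve(date_positions[date_index - 1])
    )
    return float(np.clip(value, *LAI_RANGE))


def lai_trajectory(
    density_label: str,
    nitrogen_label: str,
    date_index: int,
    seed: int,
    replicate: int = 0,
    date_positions: tuple[float, ...] = MAIN_DATE_POSITIONS,
) -> float:
    """One noisy LAI draw for a plot-date.

    Lognormal multiplicative plot noise around :func:`lai_expected`,
    clipped to the configured range.  Deterministic in ``(arguments, seed)``.
    """
    expected = lai_expected(density_label, nitrogen_label, date_index, date_positions)
    d_idx = DEFAULT_DENSITIES.index(density_label) if density_label in DEFAULT_DENSITIES else hash(density_label) % 997
    n_idx = DEFAULT_N_RATES.index(nitrogen_label) if nitrogen_label in DEFAULT_N_RATES else hash(nitrogen_label) % 997
    rng = _rng(seed, 7, d_idx, n_idx, int(replicate), int(date_index))
    value = expected * float(np.exp(rng.normal(0.0, _PLOT_NOISE_SD)))
    return float(np.clip(value, *LAI_RANGE))


def _disc_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy * dy + dx * dx <= radius * radius
    return dy[keep], dx[keep]


def render_canopy(
    lai_true: float,
    canopy_model: CanopyModel,
    image_size: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    return_mask: bool = False,
):
    """Render one plot scene as a :class:`BandStack`.

    Leaf discs of mean radius ``blob_radius_px`` are stamped at random
    positions until the soil-visible fraction falls to exp(-k_ext * LAI)
    (within one disc area).  Leaf pixels take ``leaf_spectrum`` scaled by a
    per-blob shading factor; soil pixels take ``soil_spectrum``.  All bands
    are multiplied by ``illumination_gain``, perturbed by Gaussian noise of
    sd ``noise_sd`` and clipped to [0, 1].
    """
    if lai_true <= 0:
        raise ValueError("lai_true must be positive")
    if rng is None:
        rng = _rng(0 if seed is None else seed, 11)
    cm = canopy_model
    r_mean = cm.blob_radius_px
    if image_size < 2 * int(np.ceil(r_mean)) + 1:
        raise ValueError(
            f"image_size {image_size} too small for blobs of radius {r_mean}"
        )
    target_gap = float(np.exp(-cm.k_ext * lai_true))
    n_px = image_size * image_size

    leaf = np.zeros((image_size, image_size), dtype=bool)
    shade = np.ones((image_size, image_size), dtype=np.float64)
    soil_count = n_px
    max_iter = 100 * n_px
    it = 0
    while soil_count / n_px > target_gap:
        it += 1
        if it > max_iter:  # pragma: no cover - safety valve
            raise RuntimeError("blob placement failed to reach target gap fraction")
        radius = max(1.0, rng.normal(r_mean, 0.2 * r_mean))
        cy, cx = rng.integers(0, image_size, size=2)
        dy, dx = _disc_offsets(int(round(radius)))
        yy, xx = cy + dy, cx + dx
        keep = (yy >= 0) & (yy < image_size) & (xx >= 0) & (xx < image_size)
        yy, xx = yy[keep], xx[keep]
        newly = ~leaf[yy, xx]
        soil_count -= int(newly.sum())
        leaf[yy, xx] = True
        shade[yy, xx] = float(np.exp(rng.normal(0.0, cm.shading_sd)))

    bands = {}
    for bi, name in enumerate(BAND_NAMES):
        img = np.where(leaf, cm.leaf_spectrum[bi] * shade, cm.soil_spectrum[bi])
        img = img * cm.illumination_gain
        img = img + rng.normal(0.0, cm.noise_sd, size=img.shape)
        bands[name] = np.clip(img, 0.0, 1.0)
    stack = BandStack(bands)
    if return_mask:
        return stack, leaf
    return stack


def _scenario_samples(
    design: ExperimentDesign,
    canopy_model: CanopyModel,
    scenario: str,
    scenario_key: int,
    date_positions: tuple[float, ...],
):
    records: list[SampleRecord] = []
    stacks: dict[tuple[str, int], BandStack] = {}
    seed = design.seed
    gains = _rng(seed, 3, scenario_key).uniform(*canopy_model.gain_range, size=design.dates)

    for d_idx, dl in enumerate(design.densities):
        for n_idx, nl in enumerate(design.n_rates):
            for rep in range(1, design.replicates + 1):
                plot_id = f"{dl}{nl}R{rep}"
                # per-plot soil brightness (moisture/roughness) jitter
                soil_rng = _rng(seed, 5, scenario_key, d_idx, n_idx, rep)
                soil_gain = float(np.exp(soil_rng.normal(0.0, canopy_model.soil_jitter_sd)))
                soil_spec = tuple(np.clip(np.asarray(canopy_model.soil_spectrum) * soil_gain, 0, 1))
                for date in range(1, design.dates + 1):
                    lai = lai_trajectory(
                        dl, nl, date,
                        seed=seed + 7919 * scenario_key,
                        replicate=rep,
                        date_positions=date_positions,
                    )
                    samp_rng = _rng(seed, 13, scenario_key, d_idx, n_idx, rep, date)
                    leaf_gain = np.exp(
                        samp_rng.normal(0.0, canopy_model.leaf_jitter_sd, size=len(BAND_NAMES))
                    )
                    leaf_spec = tuple(np.clip(np.asarray(canopy_model.leaf_spectrum) * leaf_gain, 0, 1))
                    cm = replace(
                        canopy_model,
                        leaf_spectrum=leaf_spec,
                        soil_spectrum=soil_spec,
                        illumination_gain=canopy_model.illumination_gain * gains[date - 1],
                    )
                    stacks[(plot_id, date)] = render_canopy(
                        lai, cm, design.image_size, rng=samp_rng
                    )
                    records.append(
                        SampleRecord(
                            plot_id=plot_id,
                            density_label=dl,
                            nitrogen_label=nl,
                            replicate=rep,
                            date_index=date,
                            lai_true=lai,
                            scenario=scenario,
                        )
                    )
    return records, stacks


def generate_experiment(design: ExperimentDesign, canopy_model: CanopyModel = CanopyModel()):
    """Generate the main-scenario trial: all plots at all dates.

    Returns ``(records, stacks)`` with one :class:`SampleRecord` per
    plot-date and a ``(plot_id, date_index) -> BandStack`` map.
    """
    positions = MAIN_DATE_POSITIONS
    if design.dates != len(positions):
        # spread custom date counts evenly across the season
        positions = tuple(np.linspace(0.3, 0.85, design.dates))
    return _scenario_samples(design, canopy_model, "main", 0, positions)


def generate_independent_scenario(
    design: ExperimentDesign, canopy_model: CanopyModel = CanopyModel()
):
    """Distribution-shifted external trial: 4 dates, darker soil, more noise."""
    design4 = replace(design, dates=4)
    shifted = replace(
        canopy_model,
        soil_spectrum=tuple(0.8 * np.asarray(canopy_model.soil_spectrum)),
        noise_sd=1.5 * canopy_model.noise_sd,
    )
    return _scenario_samples(design4, shifted, "independent", 1, INDEPENDENT_DATE_POSITIONS)
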
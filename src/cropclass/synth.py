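"""Synthetic phenology-driven multitemporal scenes with known labels.

The generator emulates the qualitative seasonal NDVI signatures of
Mediterranean cropping systems over an April-October acquisition series:

* winter crops (wheat, broad beans, oat) — green in early spring, then a
  sharp senescence drop to stubble level by early summer;
* summer crops (cotton, corn, sunflower) — bare in spring, NDVI rising to
  a mid-summer peak, then senescing, with per-crop timing offsets;
* adult tree orchards (olive, citrus, Mediterranean forest) — near
  constant canopy, flat NDVI at crop-specific levels;
* a young orchard class with sparse, slowly increasing cover;
* non-vegetation (civil works, water) — flat, low or negative NDVI.

Each class has a noise-free per-time mean for each band (Blue, Green,
Red, NIR); pixels are drawn independently as Normal(mean, sd*noise_scale)
clipped at zero. The numeric profile values are module parameters chosen
to be agronomically plausible, not measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box

from cropclass.features import MatrixData, build_matrix, extract_sbvi
from cropclass.geo_io import BAND_NAMES, Parcel, ParcelSet, RasterScene

#: Canonical noise-free NDVI trajectories, sampled at 7 evenly spaced
#: points across the season; other series lengths interpolate these.
_NDVI_CURVES: dict[str, list[float]] = {
    # winter crops differ in spring greenness/senescence timing but share
    # one stubble signature from early summer on (stubble is stubble:
    # post-harvest parcels of different winter crops are indistinguishable)
    "WHT": [0.82, 0.55, 0.28, 0.12, 0.12, 0.12, 0.12],
    "BNS": [0.72, 0.62, 0.20, 0.12, 0.12, 0.12, 0.12],
    "OAT": [0.62, 0.40, 0.16, 0.12, 0.12, 0.12, 0.12],
    "COT": [0.15, 0.20, 0.40, 0.65, 0.80, 0.60, 0.25],
    "CRN": [0.15, 0.30, 0.55, 0.80, 0.70, 0.35, 0.20],
    "SUN": [0.20, 0.45, 0.70, 0.75, 0.45, 0.25, 0.18],
    "OLV": [0.45, 0.46, 0.44, 0.45, 0.46, 0.45, 0.44],
    "CIT": [0.60, 0.61, 0.60, 0.62, 0.61, 0.60, 0.60],
    "MFO": [0.52, 0.52, 0.50, 0.51, 0.52, 0.50, 0.50],
    "YTO": [0.24, 0.26, 0.28, 0.30, 0.30, 0.28, 0.26],
    "CIV": [0.08, 0.08, 0.08, 0.08, 0.08, 0.08, 0.08],
    "WAT": [-0.10, -0.10, -0.10, -0.10, -0.10, -0.10, -0.10],
}

#: Total NIR+Red brightness per class (digital numbers): water dark,
#: built-up bright, vegetation in between.
_BRIGHTNESS: dict[str, float] = {
    "WHT": 400.0, "BNS": 400.0, "OAT": 400.0,
    "COT": 420.0, "CRN": 400.0, "SUN": 410.0,
    "OLV": 380.0, "CIT": 360.0, "MFO": 350.0,
    "YTO": 430.0, "CIV": 560.0, "WAT": 140.0,
}

_GROUPS: dict[str, str] = {
    "WHT": "winter", "BNS": "winter", "OAT": "winter",
    "COT": "summer", "CRN": "summer", "SUN": "summer",
    "OLV": "adult_orchard", "CIT": "adult_orchard", "MFO": "adult_orchard",
    "YTO": "young_orchard",
    "CIV": "nonveg", "WAT": "nonveg",
}

#: Default per-pixel, per-band Gaussian noise standard deviation (DN).
DEFAULT_NOISE_SD = 8.0

#: Background (non-parcel) band values: bare-soil-like constants.
_BACKGROUND = {"Blue": 160.0, "Gree": 170.0, "Red": 180.0, "NIR": 210.0}


@dataclass
class PhenologyProfile:
    """Noise-free per-time band means for one land-use class."""

    class_label: str
    group: str  # winter | summer | adult_orchard | young_orchard | nonveg
    band_means: dict[str, dict[str, float]]  # time -> band -> mean DN
    noise_sd: float = DEFAULT_NOISE_SD

    @property
    def times(self) -> list[str]:
        return list(self.band_means)

    def ndvi(self) -> list[float]:
        """Closed-form NDVI of the noise-free means, per time."""
        out = []
        for t in self.times:
            b = self.band_means[t]
            out.append((b["NIR"] - b["Red"]) / (b["NIR"] + b["Red"]))
        return out


def _bands_from_ndvi(v: float, brightness: float) -> dict[str, float]:
    # Red/NIR split the brightness according to NDVI; Green and Blue are
    # tied to Red via senescence (Stu = R/G) and soil (B/G) ratios that
    # drift with greenness.
    red = brightness * (1.0 - v) / 2.0
    nir = brightness * (1.0 + v) / 2.0
    stu = 1.35 - 0.5 * v  # senescent surfaces show R > G
    gree = red / stu
    blue = gree * (0.9 - 0.3 * v)
    return {"Blue": blue, "Gree": gree, "Red": red, "NIR": nir}


def check_profile(profile: PhenologyProfile) -> None:
    """Assert the declared temporal pattern of the profile's group.

    winter: NDVI(first) >= 0.6 and NDVI <= 0.25 from mid-season on;
    summer: NDVI(first) <= 0.25, peak >= 0.6 near mid-season, final <= 0.3;
    adult_orchard: max-min NDVI <= 0.15; nonveg: NDVI <= 0.2 throughout.
    """
    v = profile.ndvi()
    n = len(v)
    mid = n // 2
    group = profile.group
    ok = True
    if group == "winter":
        ok = v[0] >= 0.6 and all(x <= 0.25 for x in v[mid:])
    elif group == "summer":
        peak = max(v)
        peak_at = v.index(peak)
        ok = (v[0] <= 0.25 and peak >= 0.6 and abs(peak_at - mid) <= max(1, n // 4)
              and v[-1] <= 0.3)
    elif group == "adult_orchard":
        ok = (max(v) - min(v)) <= 0.15
    elif group == "nonveg":
        ok = all(x <= 0.2 for x in v)
    elif group == "young_orchard":
        ok = all(0.15 <= x <= 0.4 for x in v)
    else:
        raise ValueError(f"unknown group {group!r}")
    if not ok:
        raise ValueError(
            f"profile {profile.class_label} violates its {group} NDVI pattern: {v}"
        )


def default_profiles(times: list[str],
                     noise_sd: float = DEFAULT_NOISE_SD) -> list[PhenologyProfile]:
    """Twelve-class profile set spanning all cropping-system groups.

    Trajectories are interpolated onto the requested times (at least 3)
    and validated against their declared patterns.
    """
    if len(times) < 3:
        raise ValueError("need at least 3 acquisition times")
    tau = np.linspace(0.0, 1.0, len(times))
    tau7 = np.linspace(0.0, 1.0, 7)
    profiles = []
    for cls, curve in _NDVI_CURVES.items():
        v = np.interp(tau, tau7, curve)
        band_means = {
            t: _bands_from_ndvi(float(vi), _BRIGHTNESS[cls])
            for t, vi in zip(times, v)
        }
        profile = PhenologyProfile(cls, _GROUPS[cls], band_means, noise_sd)
        check_profile(profile)
        profiles.append(profile)
    return profiles


@dataclass
class SceneLayout:
    """Rectangular-parcel arrangement on a pixel grid."""

    grid_shape: tuple[int, int]
    pixel_size: float = 2.0
    origin: tuple[float, float] = (315000.0, 4186000.0)
    crs_tag: str = "UTM30N-synthetic"
    # (parcel_id, class_label, row0, col0, height, width) in pixel units
    parcels: list[tuple[str, str, int, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        occupied: set[tuple[int, int]] = set()
        for pid, _, r0, c0, h, w in self.parcels:
            if h * w < 4:
                raise ValueError(f"parcel {pid} smaller than 4 pixels")
            cells = {(r, c) for r in range(r0, r0 + h) for c in range(c0, c0 + w)}
            if cells & occupied:
                raise ValueError(f"parcel {pid} overlaps another parcel")
            occupied |= cells

    def polygon(self, entry):
        _, _, r0, c0, h, w = entry
        ox, oy = self.origin
        px = self.pixel_size
        return box(ox + c0 * px, oy - (r0 + h) * px, ox + (c0 + w) * px, oy - r0 * px)

    def parcel_set(self) -> ParcelSet:
        return ParcelSet(
            [Parcel(e[0], self.polygon(e), e[1]) for e in self.parcels],
            crs_tag=self.crs_tag,
        )


def make_layout(
    class_counts: dict[str, int],
    parcel_shape: tuple[int, int] = (12, 12),
    gap: int = 1,
    pixel_size: float = 2.0,
) -> SceneLayout:
    """Lay parcels out row-major on a near-square block grid."""
    entries = [
        (f"{cls}_{i:03d}", cls)
        for cls in class_counts
        for i in range(class_counts[cls])
    ]
    n = len(entries)
    ph, pw = parcel_shape
    bh, bw = ph + gap, pw + gap
    ncols = max(1, math.ceil(math.sqrt(n)))
    nrows = math.ceil(n / ncols)
    grid = (gap + nrows * bh, gap + ncols * bw)
    parcels = []
    for k, (pid, cls) in enumerate(entries):
        r, c = divmod(k, ncols)
        parcels.append((pid, cls, gap + r * bh, gap + c * bw, ph, pw))
    return SceneLayout(grid_shape=grid, pixel_size=pixel_size, parcels=parcels)


def generate(
    profiles: list[PhenologyProfile],
    layout: SceneLayout,
    times: list[str],
    seed: int = 0,
    noise_scale: float = 1.0,
) -> tuple[list[RasterScene], ParcelSet]:
    """Draw the scene series; deterministic for a given seed."""
    by_class = {p.class_label: p for p in profiles}
    missing = {cls for _, cls, *_ in layout.parcels} - set(by_class)
    if missing:
        raise ValueError(f"layout classes with no profile: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    ox, oy = layout.origin
    px = layout.pixel_size
    scenes = []
    for t in times:
        bands = {
            b: np.full(layout.grid_shape, _BACKGROUND[b], dtype=float)
            for b in BAND_NAMES
        }
        for pid, cls, r0, c0, h, w in layout.parcels:
            prof = by_class[cls]
            means = prof.band_means[t]
            sd = prof.noise_sd * noise_scale
            for b in BAND_NAMES:
                block = (rng.normal(means[b], sd, size=(h, w)) if sd > 0
                         else np.full((h, w), means[b]))
                bands[b][r0:r0 + h, c0:c0 + w] = np.clip(block, 0.0, None)
        scenes.append(
            RasterScene(bands, (ox, oy, px, px), crs_tag=layout.crs_tag, time_tag=t)
        )
    return scenes, layout.parcel_set()


def _stratified_split(
    labels: dict[str, str], train_fraction: float, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Seeded stratified split whose train size is ceil(fraction * N) overall."""
    by_class: dict[str, list[str]] = {}
    for pid in sorted(labels):
        by_class.setdefault(labels[pid], []).append(pid)
    for cls, ids in by_class.items():
        if len(ids) < 2:
            raise ValueError(f"class {cls} has fewer than 2 parcels")
        rng.shuffle(ids)
    total = sum(len(v) for v in by_class.values())
    target = math.ceil(train_fraction * total)
    base = {c: math.floor(train_fraction * len(v)) for c, v in by_class.items()}
    rem = {c: train_fraction * len(v) - base[c] for c, v in by_class.items()}
    extra = target - sum(base.values())
    for c in sorted(by_class, key=lambda c: (-rem[c], c))[:extra]:
        base[c] += 1
    train, test = [], []
    for c, ids in by_class.items():
        train += ids[: base[c]]
        test += ids[base[c]:]
    return train, test


def make_study(
    profiles: list[PhenologyProfile] | None = None,
    n_parcels_per_class: int | dict[str, int] = 20,
    times: list[str] | None = None,
    seed: int = 0,
    train_fraction: float = 0.5,
    noise_scale: float = 1.0,
    vi_mode: str = "per_pixel",
) -> tuple[MatrixData, MatrixData]:
    """Generate scenes, extract features, and split into train/test matrices.

    The split is stratified by class and seeded; the train set holds
    ceil(fraction * N) parcels overall. Both matrices keep the true labels
    (the test labels serve as ground truth for accuracy assessment).
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    times = times or [f"T{i}" for i in range(1, 8)]
    profiles = profiles or default_profiles(times)
    if isinstance(n_parcels_per_class, int):
        class_counts = {p.class_label: n_parcels_per_class for p in profiles}
    else:
        class_counts = dict(n_parcels_per_class)
    layout = make_layout(class_counts)
    scenes, parcels = generate(profiles, layout, times, seed=seed,
                               noise_scale=noise_scale)
    records = extract_sbvi(scenes, parcels, vi_mode=vi_mode)
    labels = parcels.labels()
    rng = np.random.default_rng(seed + 1)
    train_ids, test_ids = _stratified_split(labels, train_fraction, rng)
    matrix = build_matrix(records, labels, times)
    train = MatrixData(matrix.frame.loc[sorted(train_ids)].copy())
    test = MatrixData(matrix.frame.loc[sorted(test_ids)].copy())
    return train, test
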
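"""Parametric leg cross-section conductivity phantoms.

A phantom is a 64x64 conductivity map (S/m) of a circular leg section with
the concentric layer anatomy of the lower leg: a thin skin layer on the
outside, subcutaneous fat beneath it, and muscle occupying the interior.
Embedded in the muscle are the tibia (eccentric, cortical shell around
cancellous core), the fibula (lateral, cortical bone), blood vessels and a
nerve bundle, plus zero to three randomly placed pathologies (edema, tumor,
hematoma, foreign body).  Conductivities are drawn per structure from
literature-style ranges at 1 kHz and always lie in [0, 2] S/m.

Geometry not pinned down by the reference ranges (disc radius, bone and
anomaly sizes) is configurable; defaults are chosen so every structure is
resolvable on the 64x64 grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TissueSpec", "LegPhantom", "DatasetSplit", "default_tissues",
    "GRID_SIZE", "LEG_RADIUS_PX", "BACKGROUND_SIGMA", "LABELS",
    "generate_phantom", "generate_dataset", "split_dataset", "augment",
    "domain_mask",
]

GRID_SIZE = 64
#: leg disc radius in pixels; maximal disc leaving a 2-px electrode margin
LEG_RADIUS_PX = 30.0
#: homogeneous reference medium outside the leg (linearization baseline)
BACKGROUND_SIGMA = 1.0

LABELS = {
    "background": 0, "skin": 1, "fat": 2, "muscle": 3,
    "tibia_cortical": 4, "tibia_cancellous": 5, "fibula_cortical": 6,
    "vessel": 7, "nerve": 8, "edema": 9, "tumor": 10, "hematoma": 11,
    "foreign_body": 12,
}


@dataclass(frozen=True)
class TissueSpec:
    """Conductivity range (S/m) and geometry ranges for one tissue class."""
    name: str
    conductivity_range: tuple[float, float]
    geometry: dict = field(default_factory=dict)

    def validate(self):
        lo, hi = self.conductivity_range
        if not (0.0 <= lo <= hi <= 2.0):
            raise ValueError(
                f"{self.name}: conductivity range {self.conductivity_range} "
                "must lie inside [0, 2] S/m")


def default_tissues() -> dict[str, TissueSpec]:
    """Reference tissue configuration (conductivities at 1 kHz)."""
    t = {
        "skin": TissueSpec("skin", (0.30, 0.60),
                           {"thickness_px": (1.0, 3.0)}),
        "fat": TissueSpec("fat", (0.30, 0.55),
                          {"thickness_px": (5.0, 10.0)}),
        "muscle": TissueSpec("muscle", (0.80, 1.20), {}),
        "tibia_cortical": TissueSpec(
            "tibia_cortical", (0.05, 0.15),
            {"radius_px": (5.0, 7.0), "shell_px": (2.0, 3.0),
             "offset_frac": (0.15, 0.30)}),
        "tibia_cancellous": TissueSpec("tibia_cancellous", (0.10, 0.25), {}),
        "fibula_cortical": TissueSpec(
            "fibula_cortical", (0.05, 0.15),
            {"radius_px": (2.5, 4.0), "offset_frac": (0.55, 0.75)}),
        "vessel": TissueSpec("vessel", (1.20, 1.60),
                             {"radius_px": (1.0, 3.0), "count": (2, 3)}),
        "nerve": TissueSpec("nerve", (0.08, 0.20),
                            {"radius_px": (1.0, 3.0), "count": (1, 2)}),
        "edema": TissueSpec("edema", (0.72, 0.88), {"radius_px": (2.0, 6.0)}),
        "tumor": TissueSpec("tumor", (0.27, 0.33), {"radius_px": (2.0, 6.0)}),
        "hematoma": TissueSpec("hematoma", (0.135, 0.165),
                               {"radius_px": (2.0, 6.0)}),
        "foreign_body": TissueSpec("foreign_body", (0.005, 0.015),
                                   {"radius_px": (2.0, 6.0)}),
    }
    return t


ANOMALY_TYPES = ("edema", "tumor", "hematoma", "foreign_body")

_REQUIRED = ("skin", "fat", "muscle", "tibia_cortical", "tibia_cancellous",
             "fibula_cortical", "vessel")


@dataclass
class LegPhantom:
    conductivity: np.ndarray          # (64, 64) float64, S/m
    labels: np.ndarray                # (64, 64) int8 tissue ids
    domain_mask: np.ndarray           # (64, 64) bool, the leg disc
    anomalies: list                   # list of (type, (cy, cx), radius, sigma)
    seed: int
    skin_thickness: float = 0.0
    fat_thickness: float = 0.0


@dataclass(frozen=True)
class DatasetSplit:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def _grid_coords(n: int = GRID_SIZE):
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return yy - c, xx - c


def domain_mask(n: int = GRID_SIZE, radius: float = LEG_RADIUS_PX) -> np.ndarray:
    dy, dx = _grid_coords(n)
    return dy * dy + dx * dx < radius * radius


def _draw(rng: np.random.Generator, rangespec) -> float:
    return float(rng.uniform(rangespec[0], rangespec[1]))


def generate_phantom(seed: int, config: dict[str, TissueSpec] | None = None,
                     anomaly_probability: float = 1.0,
                     grid_size: int = GRID_SIZE,
                     radius_px: float | None = None) -> LegPhantom:
    """Generate one randomized leg phantom; bit-identical for equal seeds.

    ``anomaly_probability`` scales the chance of placing pathologies;
    with 0 the anomaly list is always empty.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    config = dict(config) if config is not None else default_tissues()
    missing = [k for k in _REQUIRED if k not in config]
    if missing:
        raise ValueError(f"config missing tissue classes: {missing}")
    for spec in config.values():
        spec.validate()

    n = grid_size
    R = radius_px if radius_px is not None else LEG_RADIUS_PX * n / GRID_SIZE
    rng = np.random.default_rng(seed)
    dy, dx = _grid_coords(n)
    dist = np.sqrt(dy * dy + dx * dx)
    disc = dist < R

    labels = np.zeros((n, n), dtype=np.int8)
    sigma = np.full((n, n), BACKGROUND_SIGMA, dtype=np.float64)

    t_skin = _draw(rng, config["skin"].geometry["thickness_px"])
    t_fat = _draw(rng, config["fat"].geometry["thickness_px"])
    r_fat_out = R - t_skin
    r_muscle_out = r_fat_out - t_fat

    def paint(mask, name):
        labels[mask] = LABELS[name]
        sigma[mask] = _draw(rng, config[name].conductivity_range)

    paint(disc, "skin")
    paint(dist < r_fat_out, "fat")
    muscle_mask = dist < r_muscle_out
    paint(muscle_mask, "muscle")

    # -- tibia: eccentric cortical shell + cancellous interior ----------
    tib = config["tibia_cortical"].geometry
    r_tib = _draw(rng, tib["radius_px"]) * n / GRID_SIZE
    shell = _draw(rng, tib["shell_px"]) * n / GRID_SIZE
    off = _draw(rng, tib["offset_frac"]) * R
    off = min(off, r_muscle_out - r_tib - 1.0)
    ang = rng.uniform(0, 2 * np.pi)
    cy, cx = off * np.sin(ang), off * np.cos(ang)
    d_tib = np.sqrt((dy - cy) ** 2 + (dx - cx) ** 2)
    paint(d_tib < r_tib, "tibia_cortical")
    paint(d_tib < max(r_tib - shell, 0.5), "tibia_cancellous")

    # -- fibula: lateral cortical bone, kept inside the muscle ring -----
    fib = config["fibula_cortical"].geometry
    r_fib = _draw(rng, fib["radius_px"]) * n / GRID_SIZE
    lo, hi = fib["offset_frac"]
    off_max = r_muscle_out - r_fib - 1.0
    off = min(_draw(rng, (lo, hi)) * R, off_max)
    ang_f = ang + np.pi + rng.uniform(-0.6, 0.6)   # roughly opposite tibia
    cy_f, cx_f = off * np.sin(ang_f), off * np.cos(ang_f)
    d_fib = np.sqrt((dy - cy_f) ** 2 + (dx - cx_f) ** 2)
    paint(d_fib < r_fib, "fibula_cortical")

    # -- vessels and nerves inside the muscle ---------------------------
    def place_small(name):
        spec = config[name]
        cnt = int(rng.integers(spec.geometry["count"][0],
                               spec.geometry["count"][1] + 1))
        for _ in range(cnt):
            r = _draw(rng, spec.geometry["radius_px"]) * n / GRID_SIZE
            for _try in range(40):
                rad = rng.uniform(0, r_muscle_out - r - 0.5)
                a = rng.uniform(0, 2 * np.pi)
                py, px = rad * np.sin(a), rad * np.cos(a)
                iy = int(round(py + (n - 1) / 2))
                ix = int(round(px + (n - 1) / 2))
                if labels[iy, ix] == LABELS["muscle"]:
                    d = np.sqrt((dy - py) ** 2 + (dx - px) ** 2)
                    paint((d < r) & (labels == LABELS["muscle"]), name)
                    break

    if "vessel" in config:
        place_small("vessel")
    if "nerve" in config:
        place_small("nerve")

    # -- pathologies (0..3) in the muscle region ------------------------
    anomalies = []
    n_anom = int(rng.integers(0, 4))
    if rng.random() >= anomaly_probability:
        n_anom = 0
    avail = [a for a in ANOMALY_TYPES if a in config]
    for _ in range(n_anom):
        if not avail:
            break
        name = avail[int(rng.integers(0, len(avail)))]
        spec = config[name]
        r = _draw(rng, spec.geometry["radius_px"]) * n / GRID_SIZE
        for _try in range(60):
            rad = rng.uniform(0, max(r_muscle_out - r - 0.5, 1.0))
            a = rng.uniform(0, 2 * np.pi)
            py, px = rad * np.sin(a), rad * np.cos(a)
            iy = int(round(py + (n - 1) / 2))
            ix = int(round(px + (n - 1) / 2))
            if labels[iy, ix] == LABELS["muscle"]:
                val = _draw(rng, spec.conductivity_range)
                d = np.sqrt((dy - py) ** 2 + (dx - px) ** 2)
                m = (d < r) & (labels == LABELS["muscle"])
                labels[m] = LABELS[name]
                sigma[m] = val
                anomalies.append((name, (float(py), float(px)), float(r), val))
                break

    sigma = np.clip(sigma, 0.0, 2.0)
    return LegPhantom(conductivity=sigma, labels=labels, domain_mask=disc,
                      anomalies=anomalies, seed=seed,
                      skin_thickness=t_skin, fat_thickness=t_fat)


def generate_dataset(n: int, base_seed: int = 0,
                     config: dict[str, TissueSpec] | None = None,
                     grid_size: int = GRID_SIZE) -> list[LegPhantom]:
    """Generate ``n`` phantoms with per-sample seeds derived from ``base_seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    root = np.random.SeedSequence(base_seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(n)]
    return [generate_phantom(s, config, grid_size=grid_size) for s in seeds]


def split_dataset(n: int, ratios=(0.8, 0.1, 0.1), seed: int = 0) -> DatasetSplit:
    """Random disjoint train/val/test index split (floor(0.8n)/floor(0.1n)/rest)."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    return DatasetSplit(train=perm[:n_train],
                        val=perm[n_train:n_train + n_val],
                        test=perm[n_train + n_val:])


def augment(inp: np.ndarray, label: np.ndarray, seed: int,
            noise_std: float = 0.01):
    """Right-angle rotation + optional horizontal flip applied to both
    images, plus a small Gaussian perturbation on the input only."""
    if inp.shape[-1] != inp.shape[-2] or inp.shape != label.shape:
        raise ValueError("augment expects square, equally shaped image pairs")
    rng = np.random.default_rng(seed)
    k = int(rng.integers(0, 4))
    flip = bool(rng.integers(0, 2))
    out_i = np.rot90(inp, k, axes=(-2, -1))
    out_l = np.rot90(label, k, axes=(-2, -1))
    if flip:
        out_i = out_i[..., ::-1]
        out_l = out_l[..., ::-1]
    if noise_std > 0:
        out_i = out_i + rng.normal(0.0, noise_std, out_i.shape)
    return np.ascontiguousarray(out_i), np.ascontiguousarray(out_l)
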
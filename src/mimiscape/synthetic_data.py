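"""Synthetic wing patterns, reflectance spectra and predation experiments.

Generates inputs with the statistical structure the downstream analysis
assumes: four-colour wing patterns for homozygote / heterozygote / exotic
morphs built from parametric patch geometry (so ground-truth areas and
distances are analytic), smooth reflectance spectra for the black / orange
/ yellow / white patch colours, and Bernoulli predation outcomes for
groups of five dummy roles placed at field sites.

Default rates mirror the headline structure of the field experiment they
emulate: local homozygous morphs attacked at ~4%, exotic and intermediate
(heterozygous) morphs at roughly twice that, a palatable cryptic control
in between, and 98.4% of dummies recovered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image

from .cpm import DEFAULT_CENTROIDS, WingImage

__all__ = [
    "PatchSpec",
    "MorphSpec",
    "DominanceBlend",
    "ExperimentDesign",
    "ROLES",
    "DEFAULT_ATTACK_PROB",
    "DEFAULT_RECOVERY_PROB",
    "render_morph",
    "blend_heterozygote",
    "make_reflectance_set",
    "simulate_predation",
    "wing_image_to_png",
    "wing_image_from_png",
    "write_predation_csv",
    "read_predation_csv",
]

ROLES = ("hom1", "hom2", "het", "exotic", "palatable")

DEFAULT_ATTACK_PROB: dict[str, float] = {
    "hom1": 0.04,
    "hom2": 0.04,
    "het": 0.08,
    "exotic": 0.08,
    "palatable": 0.045,
}
DEFAULT_RECOVERY_PROB = 0.984


# --------------------------------------------------------------------------
# Morph geometry
# --------------------------------------------------------------------------

@dataclass
class PatchSpec:
    """One geometric pattern element, in wing-fraction coordinates.

    ``kind`` is ``"ellipse"`` (axis-aligned, half-axes = ``size``) or
    ``"band"`` (horizontal stripe of half-height ``size[1]`` centred at
    ``center[1]``, spanning the wing; ``size[0]`` is its half-width about
    ``center[0]``). ``color_class`` must be one of the wing colour classes.
    """

    kind: str
    center: tuple[float, float]
    size: tuple[float, float]
    color_class: str

    def __post_init__(self) -> None:
        if self.kind not in ("ellipse", "band"):
            raise ValueError(f"unknown patch kind {self.kind!r}")
        if min(self.size) <= 0:
            raise ValueError("patch size must be positive")
        if self.color_class not in DEFAULT_CENTROIDS:
            raise ValueError(f"unknown colour class {self.color_class!r}")

    def contains(self, fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
        """Analytic membership test on fraction coordinates."""
        cx, cy = self.center
        sx, sy = self.size
        if self.kind == "ellipse":
            return ((fx - cx) / sx) ** 2 + ((fy - cy) / sy) ** 2 <= 1.0
        return (np.abs(fy - cy) <= sy) & (np.abs(fx - cx) <= sx)


@dataclass
class MorphSpec:
    """A parametric wing colour-pattern morph.

    The wing outline is an axis-aligned ellipse (half-axes ``wing_shape``
    as fractions of the image, centred); ``pattern_elements`` are painted
    in order over the ``background_class``, so every wing pixel ends with
    exactly one colour class.
    """

    name: str
    pattern_elements: list[PatchSpec] = field(default_factory=list)
    background_class: str = "black"
    wing_shape: tuple[float, float] = (0.45, 0.38)

    def __post_init__(self) -> None:
        if self.background_class not in DEFAULT_CENTROIDS:
            raise ValueError(f"unknown colour class {self.background_class!r}")
        if not (0 < self.wing_shape[0] <= 0.5 and 0 < self.wing_shape[1] <= 0.5):
            raise ValueError("wing outline must fit inside the image")

    def outline(self, fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
        ax, ay = self.wing_shape
        return ((fx - 0.5) / ax) ** 2 + ((fy - 0.5) / ay) ** 2 <= 1.0

    def to_json(self) -> str:
        return json.dumps({
            "name": self.name,
            "background_class": self.background_class,
            "wing_shape": list(self.wing_shape),
            "pattern_elements": [
                {"kind": p.kind, "center": list(p.center),
                 "size": list(p.size), "color_class": p.color_class}
                for p in self.pattern_elements
            ],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MorphSpec":
        d = json.loads(text)
        return cls(
            name=d["name"],
            background_class=d.get("background_class", "black"),
            wing_shape=tuple(d.get("wing_shape", (0.45, 0.38))),
            pattern_elements=[
                PatchSpec(kind=p["kind"], center=tuple(p["center"]),
                          size=tuple(p["size"]), color_class=p["color_class"])
                for p in d.get("pattern_elements", [])
            ],
        )


@dataclass
class DominanceBlend:
    """A heterozygote as a geometric interpolation between two parent morphs.

    ``d`` is the dominance coefficient of ``parent1``: d=1 reproduces
    parent1 exactly, d=0 reproduces parent2, intermediate values move each
    pattern element's geometry linearly between the parents.
    """

    parent1: MorphSpec
    parent2: MorphSpec
    d: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("dominance coefficient d must lie in [0, 1]")


def _fraction_grid(resolution: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = resolution
    fy, fx = np.mgrid[0:h, 0:w].astype(float)
    return (fx + 0.5) / w, (fy + 0.5) / h


def _class_index(names: tuple[str, ...], cls: str) -> int:
    return names.index(cls)


def render_morph(spec: MorphSpec, resolution: tuple[int, int] = (64, 64),
                 noise_sd: float = 0.0, seed: int | None = None,
                 side: str = "fore") -> WingImage:
    """Rasterize a morph at the given resolution.

    With ``noise_sd`` = 0 every wing pixel's RGB equals its colour-class
    centroid exactly; otherwise Gaussian jitter of that standard deviation
    is added per channel (clipped to [0, 1]). Identical seeds give
    identical images. A patch with any pixel outside the wing outline is
    rejected.
    """
    h, w = resolution
    if h < 32 or w < 32:
        raise ValueError("resolution must be at least 32 x 32")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    fx, fy = _fraction_grid(resolution)
    mask = spec.outline(fx, fy)
    names = tuple(DEFAULT_CENTROIDS)
    labels = np.full(resolution, _class_index(names, spec.background_class))
    for patch in spec.pattern_elements:
        inside = patch.contains(fx, fy)
        if np.any(inside & ~mask):
            raise ValueError(
                f"patch {patch.color_class}/{patch.kind} of morph "
                f"{spec.name!r} extends outside the wing outline"
            )
        labels[inside] = _class_index(names, patch.color_class)

    cents = np.asarray([DEFAULT_CENTROIDS[c] for c in names])
    rgb = cents[labels]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rgb = np.clip(rgb + rng.normal(0.0, noise_sd, rgb.shape), 0.0, 1.0)
    rgb[~mask] = 0.0
    return WingImage(rgb=rgb, mask=mask, side=side, specimen_id=spec.name)


def blend_heterozygote(blend: DominanceBlend,
                       resolution: tuple[int, int] = (64, 64),
                       noise_sd: float = 0.0, seed: int | None = None,
                       name: str | None = None) -> WingImage:
    """Render the heterozygote of a dominance blend.

    Each pattern element's centre and size interpolate between the parents
    with weight ``d`` on parent1; the colour class follows the parent
    carrying more weight (parent1 when d >= 0.5). Parents must share a
    wing outline and have the same number of elements, matched by index;
    to model a patch present in only one parent, give the other parent a
    background-coloured element at the matching index.
    """
    p1, p2 = blend.parent1, blend.parent2
    if p1.wing_shape != p2.wing_shape:
        raise ValueError("parents must share a wing outline")
    if len(p1.pattern_elements) != len(p2.pattern_elements):
        raise ValueError("parents must have matching pattern elements")
    d = blend.d
    if d == 1.0:
        spec = replace(p1, name=name or f"{p1.name}x{p2.name}_d1")
    elif d == 0.0:
        spec = replace(p2, name=name or f"{p1.name}x{p2.name}_d0")
    else:
        elements = []
        for e1, e2 in zip(p1.pattern_elements, p2.pattern_elements):
            if e1.kind != e2.kind:
                raise ValueError("matched pattern elements must share a kind")
            elements.append(PatchSpec(
                kind=e1.kind,
                center=(d * e1.center[0] + (1 - d) * e2.center[0],
                        d * e1.center[1] + (1 - d) * e2.center[1]),
                size=(d * e1.size[0] + (1 - d) * e2.size[0],
                      d * e1.size[1] + (1 - d) * e2.size[1]),
                color_class=e1.color_class if d >= 0.5 else e2.color_class,
            ))
        bg = p1.background_class if d >= 0.5 else p2.background_class
        spec = MorphSpec(name=name or f"{p1.name}x{p2.name}_d{d:g}",
                         pattern_elements=elements, background_class=bg,
                         wing_shape=p1.wing_shape)
    img = render_morph(spec, resolution=resolution, noise_sd=noise_sd, seed=seed)
    if name is not None:
        img.specimen_id = name
    return img


# --------------------------------------------------------------------------
# Reflectance spectra
# --------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_reflectance_set(classes: tuple[str, ...] = tuple(DEFAULT_CENTROIDS),
                         grid: np.ndarray | None = None) -> dict:
    """Smooth synthetic reflectance spectra for the wing colour classes.

    black: low flat (~5%); white: high flat (~80%); yellow: sigmoidal step
    up near 500 nm; orange: step up near 550 nm. All values in [0, 1].
    """
    from .visual_model import Spectrum

    if grid is None:
        grid = np.arange(300.0, 701.0, 5.0)
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    if grid[0] > 300.0 or grid[-1] < 700.0:
        raise ValueError("grid must cover 300-700 nm")

    recipes = {
        "black": np.full(grid.shape, 0.05),
        "white": np.full(grid.shape, 0.80),
        "yellow": 0.05 + 0.65 * _sigmoid((grid - 500.0) / 15.0),
        "orange": 0.05 + 0.70 * _sigmoid((grid - 550.0) / 15.0),
    }
    out = {}
    for cls in classes:
        if cls not in recipes:
            raise ValueError(f"no synthetic reflectance recipe for {cls!r}")
        out[cls] = Spectrum(grid, recipes[cls], kind="reflectance")
    return out


# --------------------------------------------------------------------------
# Predation experiment
# --------------------------------------------------------------------------

@dataclass
class ExperimentDesign:
    """Layout and rates of one artificial-predation experiment.

    ``sites`` maps each site id to its site-group (sites testing the same
    morph set share a group). Each station holds one dummy of each of the
    five roles; between 180 and 300 groups are placed per site. Attacks
    are independent Bernoulli draws per dummy, and each dummy is recovered
    with ``recovery_prob`` (unrecovered dummies have no attack outcome).
    """

    sites: dict[str, str]
    groups_per_site: int = 200
    roles: tuple[str, ...] = ROLES
    attack_prob: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTACK_PROB))
    recovery_prob: float = DEFAULT_RECOVERY_PROB
    seed: int = 0
    het_distance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("site list is empty")
        if not 180 <= self.groups_per_site <= 300:
            raise ValueError("groups_per_site must lie in [180, 300]")
        if len(set(self.roles)) != len(self.roles) or len(self.roles) != 5:
            raise ValueError("exactly five distinct roles per group")
        for role, p in self.attack_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"attack_prob[{role!r}] outside [0, 1]")
        if not 0.0 <= self.recovery_prob <= 1.0:
            raise ValueError("recovery_prob outside [0, 1]")


def simulate_predation(design: ExperimentDesign,
                       het_attack_fn=None) -> pd.DataFrame:
    """Simulate one predation experiment into a tidy PredationTable.

    One row per placed dummy with columns ``site, site_group, group, role,
    recovered, attacked``; ``attacked`` is defined (non-missing) only for
    recovered dummies. If ``het_attack_fn`` is given, the heterozygote's
    attack probability at each site-group is ``het_attack_fn(distance)``
    with the group's phenotypic distance to its peak taken from
    ``design.het_distance``. Fully reproducible under ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    frames = []
    for site, site_group in design.sites.items():
        n = design.groups_per_site
        for role in design.roles:
            p = design.attack_prob.get(role, 0.0)
            if het_attack_fn is not None and role == "het":
                if site_group not in design.het_distance:
                    raise KeyError(
                        f"no het distance recorded for site-group {site_group!r}")
                p = float(het_attack_fn(design.het_distance[site_group]))
                if not 0.0 <= p <= 1.0:
                    raise ValueError("het_attack_fn returned a non-probability")
            recovered = rng.random(n) < design.recovery_prob
            attacked = rng.random(n) < p
            frames.append(pd.DataFrame({
                "site": site,
                "site_group": site_group,
                "group": np.arange(n),
                "role": role,
                "recovered": recovered,
                "attacked": pd.array(
                    np.where(recovered, attacked, None), dtype="boolean"),
            }))
    table = pd.concat(frames, ignore_index=True)
    return table.sort_values(["site", "group", "role"], kind="stable",
                             ignore_index=True)


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------

def wing_image_to_png(image: WingImage, path) -> None:
    """Write an RGBA PNG; the alpha channel carries the wing mask."""
    rgba = np.dstack([
        np.clip(image.rgb * 255, 0, 255).astype(np.uint8),
        (image.mask * 255).astype(np.uint8),
    ])
    Image.fromarray(rgba, mode="RGBA").save(path)


def wing_image_from_png(path, side: str = "fore",
                        specimen_id: str = "") -> WingImage:
    arr = np.asarray(Image.open(path).convert("RGBA"), dtype=float)
    return WingImage(rgb=arr[..., :3] / 255.0, mask=arr[..., 3] > 127,
                     side=side, specimen_id=specimen_id)


def write_predation_csv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["recovered"] = out["recovered"].astype(int)
    out["attacked"] = out["attacked"].astype("Int64")
    out.to_csv(path, index=False)


def read_predation_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    table["recovered"] = table["recovered"].astype(bool)
    table["attacked"] = pd.array(table["attacked"], dtype="Int64").astype("boolean")
    return table
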
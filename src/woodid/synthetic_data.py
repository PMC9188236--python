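"""Synthetic multi-view texture datasets with a tree-level variance component.

The generator does not try to look like wood; it reproduces the statistical
structure the identification pipeline assumes and the evaluation protocols
probe:

* each species has, per anatomical view, an oriented sinusoidal grating
  (orientation theta, spatial frequency f) mixed with a species-specific
  band-pass noise texture — a phase-rich signal that the LPQ descriptor
  resolves well;
* congeneric species receive nearby parameters (orientation offsets under
  10 degrees), emulating intra-genus confusability;
* every physical tree perturbs its species' grating once per view
  (delta-theta, relative delta-f ~ Normal(0, sigma_tree^2)), so images from
  one tree are more alike than images from two trees of the same species;
* each image adds independent pixel noise of standard deviation sigma_image.

Setting sigma_tree large and sigma_image small creates exactly the leakage
trap that grouped cross-validation exposes; sigma_tree = 0 removes it.  The
``complementary`` flag makes each view carry an independent digit of the
species code, so no single view can identify a species but the three views
jointly can — the regime in which multi-view fusion must beat any
single-view model.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .lpq import LPQConfig, lpq_descriptor
from .taxonomy_io import (
    VIEWS,
    DatasetIndex,
    ImageRecord,
    TaxonomyTable,
    save_manifest,
)


@dataclass(frozen=True)
class SynthConfig:
    n_families: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 2
    trees_per_species: int = 4
    images_per_tree: int = 4
    image_size: int = 128
    view_informative: tuple = (True, True, True)
    complementary: bool = False
    sigma_tree: float = 0.05
    sigma_image: float = 0.10
    texture_weight: tuple = (0.15, 0.30)   # range of the band-pass mixing weight
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_families", "genera_per_family", "species_per_genus",
                     "trees_per_species", "images_per_tree"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sigma_tree < 0:
            raise ValueError("sigma_tree must be >= 0")
        if self.sigma_image < 0:
            raise ValueError("sigma_image must be >= 0")
        if len(self.view_informative) != 3:
            raise ValueError("view_informative needs one flag per view")

    @property
    def q(self) -> int:
        return self.n_families * self.genera_per_family * self.species_per_genus


@dataclass(frozen=True)
class GratingParams:
    """Texture parameters of one (species, view): an oriented grating plus
    a deterministic band-pass noise component mixed in with weight w."""

    theta: float          # orientation, radians in [0, pi)
    freq: float           # spatial frequency, cycles per pixel
    weight: float         # band-pass texture mixing weight in [0, 1]
    texture_seed: int     # seed of the shared band-pass texture


def _species_names(cfg: SynthConfig) -> tuple[TaxonomyTable, list[str]]:
    entries = {}
    order = []
    s = 0
    for fi in range(cfg.n_families):
        fam = f"Family{fi:02d}"
        for gi in range(cfg.genera_per_family):
            genus = f"Genus{fi:02d}_{gi:02d}"
            for si in range(cfg.species_per_genus):
                name = f"{genus} sp{si:02d}"
                entries[name] = (genus, fam)
                order.append(name)
                s += 1
    return TaxonomyTable(entries), order


def sample_species_params(cfg: SynthConfig):
    """Draw per-(species, view) grating parameters and the taxonomy.

    In the default regime each genus gets a base orientation per view
    (spread over [0, pi)) and congeners sit within +-5 degrees of it.  In
    the complementary regime species index s is decomposed into three
    digits and view v's parameters depend on digit v only, so each view
    carries one digit of information and none identifies a species alone.
    An uninformative view shares one parameter set across all species.
    """
    tax, order = _species_names(cfg)
    rng = np.random.default_rng(cfg.seed)
    q = cfg.q
    params: dict[str, dict[str, GratingParams]] = {sp: {} for sp in order}

    def tex_seed(view: str, theta: float, freq: float) -> int:
        # species sharing grating parameters must share the texture too,
        # otherwise the texture itself would leak species identity
        key = f"{view}|{theta:.8f}|{freq:.8f}|{cfg.seed}"
        return zlib.crc32(key.encode()) % 2**31

    weights = {
        (sp, v): float(rng.uniform(*cfg.texture_weight))
        for sp in order for v in VIEWS
    }

    if cfg.complementary:
        base = 2
        while base ** 3 < q:
            base += 1
        freq_per_view = rng.uniform(0.08, 0.16, size=3)
        for s, sp in enumerate(order):
            digits = [(s // base**v) % base for v in range(3)]
            for v, view in enumerate(VIEWS):
                theta = np.pi * (digits[v] + 0.5) / base
                f = float(freq_per_view[v])
                params[sp][view] = GratingParams(
                    float(theta), f, weights[(sp, view)], tex_seed(view, theta, f)
                )
        # one shared weight per (view, digit) so weight cannot leak identity
        for s, sp in enumerate(order):
            for v, view in enumerate(VIEWS):
                p = params[sp][view]
                shared = 0.5 * sum(cfg.texture_weight)
                params[sp][view] = GratingParams(p.theta, p.freq, shared, p.texture_seed)
        return params, tax

    n_genera = cfg.n_families * cfg.genera_per_family
    for v, view in enumerate(VIEWS):
        if not cfg.view_informative[v]:
            theta = float(rng.uniform(0, np.pi))
            f = float(rng.uniform(0.08, 0.18))
            shared = GratingParams(theta, f, 0.2, tex_seed(view, theta, f))
            for sp in order:
                params[sp][view] = shared
            continue
        genus_order = rng.permutation(n_genera)
        genus_theta = {g: np.pi * (rank + 0.5) / n_genera
                       for rank, g in enumerate(genus_order)}
        genus_freq = {g: float(rng.uniform(0.08, 0.18)) for g in range(n_genera)}
        gi = -1
        last_genus = None
        for sp in order:
            genus = tax.genus(sp)
            if genus != last_genus:
                gi += 1
                last_genus = genus
            offset = float(rng.uniform(-np.deg2rad(5), np.deg2rad(5)))
            fmul = float(rng.uniform(0.97, 1.03))
            theta = (genus_theta[gi] + offset) % np.pi
            f = genus_freq[gi] * fmul
            params[sp][view] = GratingParams(
                theta, f, weights[(sp, view)], tex_seed(view, theta, f)
            )
    return params, tax


@lru_cache(maxsize=256)
def _bandpass_texture(seed: int, size: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((size, size))
    band = gaussian_filter(white, 1.2) - gaussian_filter(white, 3.5)
    return band / band.std()


def sample_tree_effects(cfg: SynthConfig, rng: np.random.Generator):
    """delta-theta and relative delta-freq per (species, tree, view)."""
    eff = {}
    tax, order = _species_names(cfg)
    for sp in order:
        for t in range(cfg.trees_per_species):
            for view in VIEWS:
                eff[(sp, t, view)] = (
                    float(rng.normal(0, cfg.sigma_tree)),
                    float(rng.normal(0, cfg.sigma_tree)),
                )
    return eff


def render_image(
    p: GratingParams,
    tree_effect: tuple[float, float],
    size: int,
    sigma_image: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One grayscale image: perturbed grating + texture + pixel noise."""
    dtheta, dfreq = tree_effect
    theta = p.theta + dtheta
    f = p.freq * (1.0 + dfreq)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    arg = 2.0 * np.pi * f * (xx * np.cos(theta) + yy * np.sin(theta))
    signal = (1.0 - p.weight) * np.sin(arg)
    signal = signal + p.weight * _bandpass_texture(p.texture_seed, size)
    img = 0.5 + 0.4 * signal
    if sigma_image > 0:
        img = img + rng.normal(0.0, sigma_image, size=(size, size))
    return np.clip(img, 0.0, 1.0)


def _iter_specimens(cfg: SynthConfig):
    """Yield (species, tree_index, image_index) in deterministic order."""
    _, order = _species_names(cfg)
    for sp in order:
        for t in range(cfg.trees_per_species):
            for i in range(cfg.images_per_tree):
                yield sp, t, i


def render_dataset_arrays(cfg: SynthConfig):
    """Render the whole dataset in memory.

    Returns ``(specimens, taxonomy)`` where specimens is a list of dicts
    with keys species, tree_id, specimen_id and one image per view.
    """
    params, tax = sample_species_params(cfg)
    master = np.random.default_rng(cfg.seed + 1)
    effects = sample_tree_effects(cfg, master)
    noise_rng = np.random.default_rng(cfg.seed + 2)
    out = []
    for sp, t, i in _iter_specimens(cfg):
        slug = sp.replace(" ", "_")
        tree_id = f"{slug}/t{t}"
        spec_id = f"{slug}_t{t}_i{i}"
        images = {
            view: render_image(
                params[sp][view], effects[(sp, t, view)],
                cfg.image_size, cfg.sigma_image, noise_rng,
            )
            for view in VIEWS
        }
        out.append(dict(species=sp, tree_id=tree_id, specimen_id=spec_id, images=images))
    return out, tax


def generate_dataset(cfg: SynthConfig, out_dir: str | Path) -> DatasetIndex:
    """Render the dataset to PNG files plus a manifest CSV; reproducible."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specimens, tax = render_dataset_arrays(cfg)
    records = []
    for spec in specimens:
        for view in VIEWS:
            image_id = f"{spec['specimen_id']}_{view}"
            fname = f"{image_id}.png"
            img = (spec["images"][view] * 255).astype(np.uint8)
            iio.imwrite(out_dir / fname, img)
            records.append(
                ImageRecord(
                    image_id=image_id, path=fname, species=spec["species"],
                    tree_id=spec["tree_id"], view=view,
                    specimen_id=spec["specimen_id"],
                )
            )
    index = DatasetIndex(records, tax, root=out_dir)
    save_manifest(index, out_dir / "manifest.csv")
    return index


def generate_specimen_table(cfg: SynthConfig, lpq_cfg: LPQConfig | None = None):
    """Render the dataset and extract LPQ features without touching disk.

    Returns ``(SpecimenTable, TaxonomyTable)`` ready for
    :func:`woodid.cv_eval.run_experiment`.
    """
    import pandas as pd

    from .cv_eval import SpecimenTable

    specimens, tax = render_dataset_arrays(cfg)
    rows = []
    mats = {v: [] for v in VIEWS}
    for spec in specimens:
        rows.append(dict(
            group_id=f"{spec['specimen_id']}#p0",
            species=spec["species"], tree_id=spec["tree_id"],
        ))
        for v in VIEWS:
            mats[v].append(lpq_descriptor(spec["images"][v], lpq_cfg))
    meta = pd.DataFrame(rows)
    return SpecimenTable(meta, {v: np.vstack(mats[v]) for v in VIEWS}), tax


# ---------------------------------------------------------------------------
# presets: the three regimes the evaluation protocols are designed around

def preset_complementary(seed: int = 0) -> SynthConfig:
    """q = 10 species whose views are complementary: each view carries one
    digit of the species code, so multi-view fusion is required."""
    return SynthConfig(
        n_families=5, genera_per_family=1, species_per_genus=2,
        trees_per_species=4, images_per_tree=4,
        complementary=True, sigma_tree=0.02, sigma_image=0.06, seed=seed,
    )


def preset_tree_effect(seed: int = 0) -> SynthConfig:
    """Strong tree-level perturbations: naive k-fold CV leaks and flatters."""
    return SynthConfig(
        n_families=2, genera_per_family=2, species_per_genus=2,
        trees_per_species=4, images_per_tree=4,
        sigma_tree=0.25, sigma_image=0.05, seed=seed,
    )


def preset_null(seed: int = 0) -> SynthConfig:
    """No tree effect: naive and grouped CV estimate the same quantity."""
    return SynthConfig(
        n_families=2, genera_per_family=2, species_per_genus=2,
        trees_per_species=4, images_per_tree=4,
        sigma_tree=0.0, sigma_image=0.35, seed=seed,
    )


PRESETS = {
    "complementary": preset_complementary,
    "tree-effect": preset_tree_effect,
    "null": preset_null,
}

__all__ = [
    "SynthConfig", "GratingParams", "PRESETS",
    "sample_species_params", "sample_tree_effects", "render_image",
    "render_dataset_arrays", "generate_dataset", "generate_specimen_table",
    "preset_complementary", "preset_tree_effect", "preset_null",
]
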
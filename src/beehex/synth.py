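"""Synthetic floral communities, spectra, trees and traits.

Generators for every input the analysis consumes, so the whole pipeline
is testable without measured data: smooth flower reflectance curves built
from sigmoid/Gaussian components that land in chosen hexagon sectors,
right-skewed (log-normal) per-flower sugar amounts on the hundreds-of-μg
scale, and ultrametric pure-birth trees with traits evolved under a
λ-transformed Brownian process.  Every generator is a pure function of
its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .phylo import lambda_transform, phylo_vcv
from .spectra import (
    MODEL_GRID,
    SpectralFunction,
    make_illuminant,
    make_leaf_background,
)
from .vision import spectrum_to_locus

__all__ = [
    "FlowerArchetype",
    "ARCHETYPES",
    "CommunitySpec",
    "make_illuminant",
    "make_leaf_background",
    "make_flower_spectrum",
    "make_community",
    "simulate_tree_and_trait",
    "write_study_bundle",
]


@dataclass(frozen=True)
class FlowerArchetype:
    """Parametric reflectance shape for one flower colour type.

    Reflectance is a long-pass sigmoid plateau plus an optional Gaussian
    peak plus an optional UV bump (Gaussian at 350 nm), clipped to [0, 1]:
    smooth by construction.
    """

    name: str
    sigmoid_inflection_nm: float = 0.0
    sigmoid_slope_nm: float = 15.0
    plateau: float = 0.0
    gauss_centre_nm: float = 0.0
    gauss_width_nm: float = 40.0
    gauss_height: float = 0.0
    uv_bump: float = 0.0
    baseline: float = 0.02

    def reflectance(self, grid: np.ndarray | None = None) -> SpectralFunction:
        lam = MODEL_GRID if grid is None else np.asarray(grid, dtype=float)
        vals = np.full_like(lam, self.baseline)
        if self.plateau > 0:
            vals = vals + self.plateau / (
                1.0 + np.exp(-(lam - self.sigmoid_inflection_nm) / self.sigmoid_slope_nm)
            )
        if self.gauss_height > 0:
            vals = vals + self.gauss_height * np.exp(
                -(((lam - self.gauss_centre_nm) / self.gauss_width_nm) ** 2)
            )
        if self.uv_bump > 0:
            vals = vals + self.uv_bump * np.exp(-(((lam - 350.0) / 30.0) ** 2))
        return SpectralFunction(lam, np.clip(vals, 0.0, 1.0))


#: Six named shapes covering the hexagon: five sectors densely, UV sparsely
#: (UV flowers are rare in real communities).  Names describe the human
#: colour impression; the sector is the bee's classification.
ARCHETYPES: dict[str, FlowerArchetype] = {
    a.name: a
    for a in (
        # low <400 nm, high plateau from ~450 nm: human white, bee BG
        FlowerArchetype("uv_absorbing_white", sigmoid_inflection_nm=430.0,
                        plateau=0.75),
        # single blue peak, UV-absorbing: bee B
        FlowerArchetype("blue", gauss_centre_nm=445.0, gauss_width_nm=35.0,
                        gauss_height=0.55),
        # blue peak plus UV reflectance: bee UB
        FlowerArchetype("uv_blue", gauss_centre_nm=450.0, gauss_width_nm=35.0,
                        gauss_height=0.5, uv_bump=0.45),
        # long-pass from ~510 nm, UV-absorbing: human yellow, bee G
        FlowerArchetype("yellow", sigmoid_inflection_nm=515.0, plateau=0.7),
        # yellow plateau plus UV bump: bee UG
        FlowerArchetype("uv_reflecting_yellow", sigmoid_inflection_nm=515.0,
                        plateau=0.65, uv_bump=0.5),
        # UV bump only: bee U
        FlowerArchetype("uv", uv_bump=0.6, baseline=0.015),
    )
}

#: Archetypes to try, per target sector, during community generation.
_SECTOR_ARCHETYPES = {
    "BG": ["uv_absorbing_white"],
    "B": ["blue"],
    "UB": ["uv_blue"],
    "G": ["yellow"],
    "UG": ["uv_reflecting_yellow"],
    "U": ["uv"],
}


def make_flower_spectrum(
    archetype: FlowerArchetype | str,
    jitter: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> SpectralFunction:
    """One flower's reflectance: archetype shape with seeded perturbations.

    ``jitter`` (0 = deterministic) scales normal perturbations of the
    shape parameters: ±10·jitter nm on positions, multiplicative on
    amplitudes.  Output stays in [0, 1].
    """
    if isinstance(archetype, str):
        archetype = ARCHETYPES[archetype]
    if jitter == 0.0:
        return archetype.reflectance()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    a = archetype
    perturbed = FlowerArchetype(
        name=a.name,
        sigmoid_inflection_nm=a.sigmoid_inflection_nm + 10.0 * jitter * rng.standard_normal(),
        sigmoid_slope_nm=max(a.sigmoid_slope_nm * (1 + 0.3 * jitter * rng.standard_normal()), 5.0),
        plateau=np.clip(a.plateau * (1 + jitter * rng.standard_normal()), 0.0, 1.0),
        gauss_centre_nm=a.gauss_centre_nm + 10.0 * jitter * rng.standard_normal(),
        gauss_width_nm=max(a.gauss_width_nm * (1 + 0.3 * jitter * rng.standard_normal()), 10.0),
        gauss_height=np.clip(a.gauss_height * (1 + jitter * rng.standard_normal()), 0.0, 1.0),
        uv_bump=np.clip(a.uv_bump * (1 + jitter * rng.standard_normal()), 0.0, 1.0),
        baseline=float(np.clip(a.baseline * (1 + jitter * rng.standard_normal()), 0.005, 0.1)),
    )
    return perturbed.reflectance()


# The community observed at the two Australian field sites: 59 species,
# blue-green dominated, a single UV species, 3 Asteraceae, 28 orchids.
_DEFAULT_SECTOR_COUNTS = {"BG": 21, "B": 10, "UB": 7, "U": 1, "UG": 11, "G": 9}


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic flowering community.

    Sugar per flower is log-normal with median ``sugar_median_ug`` (μg)
    and log-scale ``sugar_sigma_log``; ``sector_effects`` multiply the
    median per sector (all 1 → the null: sugar independent of colour).
    """

    n_species: int = 59
    sector_counts: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_SECTOR_COUNTS)
    )
    n_asteraceae: int = 3
    n_orchidaceae: int = 28
    sugar_median_ug: float = 392.0
    sugar_sigma_log: float = 0.9
    sector_effects: dict[str, float] = field(default_factory=dict)
    jitter: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.sector_counts.values()) != self.n_species:
            raise ValueError("sector counts must sum to n_species")
        if self.sugar_sigma_log <= 0:
            raise ValueError("sugar_sigma_log must be positive")


def make_community(
    spec: CommunitySpec | None = None,
) -> tuple[pd.DataFrame, dict[str, SpectralFunction]]:
    """Generate a synthetic community: species records plus their spectra.

    Spectra are rejection-sampled from the sector's archetype (jittered)
    until the colour model classifies them into the requested sector;
    an archetype that cannot reach its sector raises.  Returns the
    canonical records DataFrame and a dict of spectra by species name.
    """
    spec = CommunitySpec() if spec is None else spec
    rng = np.random.default_rng(spec.seed)

    rows = []
    spectra: dict[str, SpectralFunction] = {}
    sp_idx = 0
    for sector in ("BG", "B", "UB", "U", "UG", "G"):
        count = spec.sector_counts.get(sector, 0)
        names = _SECTOR_ARCHETYPES[sector]
        for _ in range(count):
            locus = spectrum = None
            for attempt in range(200):
                arch = names[attempt % len(names)]
                candidate = make_flower_spectrum(arch, spec.jitter, rng)
                cand_locus = spectrum_to_locus(candidate)
                if cand_locus.sector == sector:
                    locus, spectrum = cand_locus, candidate
                    break
            if locus is None:
                raise RuntimeError(
                    f"archetypes for sector {sector} failed to produce a "
                    f"{sector} locus in 200 attempts (unattainable mix)"
                )
            sp_idx += 1
            name = f"sp{sp_idx:03d}_{sector}"
            effect = spec.sector_effects.get(sector, 1.0)
            sugar = spec.sugar_median_ug * effect * float(
                np.exp(spec.sugar_sigma_log * rng.standard_normal())
            )
            spectra[name] = spectrum
            rows.append(
                {
                    "species": name,
                    "family": "",  # filled below
                    "site": "BM" if rng.random() < 0.5 else "BW",
                    "sugar_ug": sugar,
                    "x": locus.x,
                    "y": locus.y,
                    "hue_deg": locus.hue_deg,
                    "contrast": locus.contrast,
                    "sector": locus.sector,
                }
            )

    frame = pd.DataFrame(rows)
    # Family labels: Asteraceae and Orchidaceae drawn from non-UV species
    # (the UV species belongs to neither special family), remainder generic.
    non_uv = frame.index[frame["sector"] != "U"].to_numpy()
    n_special = spec.n_asteraceae + spec.n_orchidaceae
    if n_special > len(non_uv):
        raise ValueError("not enough non-UV species for the requested families")
    chosen = rng.choice(non_uv, size=n_special, replace=False)
    families = np.array(
        [f"Family{(i % 12) + 1:02d}" for i in range(len(frame))], dtype=object
    )
    families[chosen[: spec.n_asteraceae]] = "Asteraceae"
    families[chosen[spec.n_asteraceae :]] = "Orchidaceae"
    frame["family"] = families
    return frame, spectra


def _yule_tree(n_tips: int, rng: np.random.Generator, birth_rate: float = 1.0) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with ``n_tips`` tips."""
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    # active lineages as (node, birth_time)
    tree.seed_node.birth_time = 0.0
    active = [tree.seed_node]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        node.split_time = t
        for _ in range(2):
            child = dendropy.Node()
            child.birth_time = t
            node.add_child(child)
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * len(active)))  # stem of the tips
    for i, leaf in enumerate(active):
        leaf.taxon = taxa[i]
        leaf.edge.length = t - leaf.birth_time
    for node in tree.preorder_internal_node_iter():
        # an internal edge spans from the node's birth to its own split
        node.edge.length = node.split_time - node.birth_time
    tree.seed_node.edge.length = 0.0  # clock starts at the first split
    for node in tree.preorder_node_iter():
        if hasattr(node, "birth_time"):
            del node.birth_time
        if hasattr(node, "split_time"):
            del node.split_time
    return tree


def simulate_tree_and_trait(
    n_tips: int,
    lam: float = 1.0,
    sigma2: float = 1.0,
    seed: int = 0,
    root_state: float = 0.0,
) -> tuple[dendropy.Tree, dict[str, float]]:
    """Ultrametric pure-birth tree with a λ-Brownian trait at the tips.

    The trait is drawn from N(root_state·1, σ²·C_λ) where C is the
    tree's Brownian covariance and C_λ its Pagel transform; λ = 0 gives
    phylogenetically independent tips, λ = 1 pure Brownian motion.
    """
    if n_tips < 4:
        raise ValueError("need at least 4 tips")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tree = _yule_tree(n_tips, rng)
    cov = lambda_transform(phylo_vcv(tree), lam)
    chol = np.linalg.cholesky(sigma2 * cov + 1e-12 * np.eye(n_tips))
    values = root_state + chol @ rng.standard_normal(n_tips)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    return tree, dict(zip(labels, values.tolist()))


def write_study_bundle(
    outdir: str | Path,
    spec: CommunitySpec | None = None,
    lam: float = 0.8,
    sigma2: float = 1.0,
) -> dict:
    """Write a complete synthetic study to ``outdir``.

    Produces spectra.csv (long form), records.csv, tree.nwk and
    manifest.json.  The tree's tips are relabelled with the community's
    species names and the trait is discarded (records carry the sugar
    values); the manifest records every parameter and seed.
    """
    spec = CommunitySpec() if spec is None else spec
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    frame, spectra = make_community(spec)
    long_rows = []
    for name, sf in spectra.items():
        for wl, val in zip(sf.wavelengths_nm, sf.values):
            long_rows.append(
                {"species": name, "patch": 1, "wavelength_nm": wl,
                 "reflectance_pct": 100.0 * val}
            )
    pd.DataFrame(long_rows).to_csv(outdir / "spectra.csv", index=False)
    frame.to_csv(outdir / "records.csv", index=False)

    tree, _ = simulate_tree_and_trait(spec.n_species, lam, sigma2, seed=spec.seed + 1)
    for leaf, name in zip(tree.leaf_node_iter(), frame["species"]):
        leaf.taxon.label = name
    tree.write(path=str(outdir / "tree.nwk"), schema="newick")

    manifest = {
        "community": asdict(spec),
        "tree": {"lambda": lam, "sigma2": sigma2, "seed": spec.seed + 1},
        "files": ["spectra.csv", "records.csv", "tree.nwk"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
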
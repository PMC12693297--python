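"""Synthetic image families and toy SMILES sets for offline testing.

Real inputs for this model are DFT-derived: molecular electrostatic
potential (MEP) surfaces and reduced-density-gradient (RDG) scatter
diagrams. This module emulates their *visual statistics* — not their
physics — so every pipeline stage runs without quantum-chemistry data:

* a **MEP-like** image is a smooth field of colored Gaussian blobs on a
  pale background; a *family* shares a blob layout, and members jitter
  the blob centers and widths;
* an **RDG-like** image is a mostly-white page with dark vertical point
  spikes at family-specific abscissae plus a diffuse top band, mimicking
  the spike structure of RDG-versus-density plots;
* each family carries a hand-curated SMILES scaffold series (linear
  alkanes; oligoethylene glycols) pre-validated so intra-family Tanimoto
  is ≥ 0.70 and inter-family ≤ 0.40 — the default triplet-mining
  thresholds are guaranteed productive.

All outputs are bit-reproducible for fixed (seed, family, member).
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import zoom

from .fingerprints import Compound, similarity_matrix
from .texture import GLCMExtractor

__all__ = [
    "FamilySpec",
    "default_family_specs",
    "make_mep_image",
    "make_rdg_image",
    "make_benchmark",
    "MEMBER_CORRELATION_FLOOR",
]

#: Minimum expected pixel correlation between two members of one family.
MEMBER_CORRELATION_FLOOR = 0.5

_MIN_SIZE = 32


@dataclass(frozen=True)
class FamilySpec:
    """Layout and chemistry of one synthetic compound family."""

    family_id: str
    n_members: int
    blob_centers: tuple[tuple[float, float], ...]  # (y, x) in [0, 1]
    blob_widths: tuple[float, ...]  # fraction of image size
    blob_colors: tuple[tuple[float, float, float], ...]  # RGB in [0, 1]
    rdg_clusters: tuple[float, ...]  # spike abscissae in [0, 1]
    smiles_pool: tuple[str, ...]
    jitter: float = 0.04

    def __post_init__(self) -> None:
        if not (
            len(self.blob_centers) == len(self.blob_widths) == len(self.blob_colors)
        ):
            raise ValueError("blob centers, widths, and colors must align")
        if not self.smiles_pool:
            raise ValueError("smiles_pool must be non-empty")


def default_family_specs() -> tuple[FamilySpec, FamilySpec]:
    """The two curated families used by the benchmark.

    'alk' (linear alkanes C6–C13): three broad warm blobs, two RDG
    spikes. 'peg' (di- to nona-ethylene glycol): five small cool blobs,
    four RDG spikes.
    """
    alk = FamilySpec(
        family_id="alk",
        n_members=8,
        blob_centers=((0.30, 0.35), (0.60, 0.65), (0.75, 0.30)),
        blob_widths=(0.22, 0.18, 0.14),
        blob_colors=((0.85, 0.15, 0.10), (0.10, 0.25, 0.85), (0.95, 0.60, 0.10)),
        rdg_clusters=(0.25, 0.70),
        smiles_pool=tuple("C" * n for n in range(6, 14)),
    )
    peg = FamilySpec(
        family_id="peg",
        n_members=8,
        blob_centers=(
            (0.20, 0.20),
            (0.20, 0.80),
            (0.50, 0.50),
            (0.80, 0.20),
            (0.80, 0.80),
        ),
        blob_widths=(0.08, 0.08, 0.10, 0.08, 0.08),
        blob_colors=(
            (0.10, 0.70, 0.30),
            (0.20, 0.80, 0.70),
            (0.60, 0.20, 0.70),
            (0.15, 0.60, 0.25),
            (0.50, 0.75, 0.15),
        ),
        rdg_clusters=(0.15, 0.40, 0.60, 0.85),
        smiles_pool=tuple("OCCO" + "CCO" * k for k in range(1, 9)),
    )
    return alk, peg


def _rng(spec: FamilySpec, member_idx: int, seed: int) -> np.random.Generator:
    fam_hash = zlib.crc32(spec.family_id.encode())
    return np.random.default_rng([seed, fam_hash, member_idx])


def make_mep_image(
    spec: FamilySpec, member_idx: int, seed: int = 0, size: int = 128
) -> np.ndarray:
    """Render one member's MEP-like image as a (size, size, 3) uint8 array."""
    if size < _MIN_SIZE:
        raise ValueError(f"size must be >= {_MIN_SIZE}, got {size}")
    rng = _rng(spec, member_idx, seed)
    yy, xx = np.meshgrid(
        np.linspace(0, 1, size), np.linspace(0, 1, size), indexing="ij"
    )
    img = np.full((size, size, 3), 0.95)
    for (cy, cx), w, color in zip(
        spec.blob_centers, spec.blob_widths, spec.blob_colors
    ):
        cy = cy + rng.normal(0, spec.jitter)
        cx = cx + rng.normal(0, spec.jitter)
        w = w * float(np.exp(rng.normal(0, spec.jitter)))
        g = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * w**2)))
        img = img * (1 - g[..., None]) + g[..., None] * np.asarray(color)
    # faint smooth luminance ripple so members are correlated, not identical
    coarse = rng.normal(0, 0.015, size=(8, 8))
    img = img + zoom(coarse, size / 8, order=1)[..., None]
    return (np.clip(img, 0, 1) * 255).round().astype(np.uint8)


def make_rdg_image(
    spec: FamilySpec, member_idx: int, seed: int = 0, size: int = 128
) -> np.ndarray:
    """Render one member's RDG-like scatter diagram (white background)."""
    if size < _MIN_SIZE:
        raise ValueError(f"size must be >= {_MIN_SIZE}, got {size}")
    rng = _rng(spec, member_idx, seed + 10_000)
    img = np.ones((size, size, 3))
    pts_y: list[np.ndarray] = []
    pts_x: list[np.ndarray] = []
    # vertical spikes descending from the band toward low y
    for x0 in spec.rdg_clusters:
        x0 = x0 + rng.normal(0, spec.jitter * 0.5)
        n = 4 * size
        pts_x.append(x0 + rng.normal(0, 0.012, n))
        pts_y.append(rng.uniform(0.25, 0.95, n))
    # diffuse top band (the dense bulk of an RDG plot)
    n_band = 6 * size
    pts_x.append(rng.uniform(0.05, 0.95, n_band))
    pts_y.append(0.18 + rng.normal(0, 0.03, n_band))
    ix = np.clip((np.concatenate(pts_x) * size).astype(int), 0, size - 1)
    iy = np.clip(((1 - np.concatenate(pts_y)) * size).astype(int), 0, size - 1)
    shade = rng.uniform(0.0, 0.35, ix.shape[0])
    img[iy, ix, 0] = shade * 0.3
    img[iy, ix, 1] = shade * 0.5
    img[iy, ix, 2] = np.minimum(0.6 + shade, 1.0) * 0.9
    return (np.clip(img, 0, 1) * 255).round().astype(np.uint8)


def _check_thresholds(
    sim: pd.DataFrame, families: dict[str, list[str]], pos: float, neg: float
) -> None:
    bad: list[str] = []
    for fam, ids in families.items():
        for a, b in itertools.combinations(ids, 2):
            if sim.loc[a, b] < pos:
                bad.append(f"intra {fam}: {a}-{b} = {sim.loc[a, b]:.3f} < {pos}")
    for fa, fb in itertools.combinations(families, 2):
        for a in families[fa]:
            for b in families[fb]:
                if sim.loc[a, b] > neg:
                    bad.append(f"inter {fa}/{fb}: {a}-{b} = {sim.loc[a, b]:.3f} > {neg}")
    if bad:
        raise ValueError(
            "SMILES pools violate the triplet threshold contract:\n" + "\n".join(bad)
        )


def _check_glcm_separation(
    features: dict[str, np.ndarray], families: dict[str, list[str]]
) -> None:
    within, between = [], []
    ids = [i for ids in families.values() for i in ids]
    fam_of = {i: f for f, ids_ in families.items() for i in ids_}
    for a, b in itertools.combinations(ids, 2):
        d = float(np.linalg.norm(features[a] - features[b]))
        (within if fam_of[a] == fam_of[b] else between).append(d)
    if np.mean(within) >= np.mean(between):
        raise ValueError(
            "generator self-test failed: mean within-family GLCM distance "
            f"({np.mean(within):.4f}) not below between-family "
            f"({np.mean(between):.4f})"
        )


def make_benchmark(
    out_dir: str | Path,
    n_families: int = 2,
    per_family: int = 8,
    seed: int = 0,
    size: int = 128,
    pos_thresh: float = 0.70,
    neg_thresh: float = 0.40,
) -> pd.DataFrame:
    """Generate the 2-family benchmark: images on disk plus a manifest.

    Writes ``manifest.csv`` (columns ``id,smiles,mep_path,rdg_path``) and
    one MEP plus one RDG PNG per compound into ``out_dir``. The generator
    self-tests its own contract before returning: intra-family Tanimoto
    ≥ ``pos_thresh``, inter-family ≤ ``neg_thresh``, and within-family
    GLCM feature distance below between-family on average.

    Only the two curated families are available (their SMILES pools are
    validated scaffold series; arbitrary families cannot guarantee the
    threshold contract).
    """
    specs = default_family_specs()
    if not (2 <= n_families <= len(specs)):
        raise ValueError(
            f"n_families must be 2 (only {len(specs)} curated families exist)"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    families: dict[str, list[str]] = {}
    features: dict[str, np.ndarray] = {}
    extractor = GLCMExtractor().fit()
    for spec in specs[:n_families]:
        if per_family > len(spec.smiles_pool):
            raise ValueError(
                f"per_family={per_family} exceeds pool size "
                f"{len(spec.smiles_pool)} for family {spec.family_id!r}"
            )
        families[spec.family_id] = []
        for m in range(per_family):
            cid = f"{spec.family_id}{m}"
            mep = make_mep_image(spec, m, seed, size)
            rdg = make_rdg_image(spec, m, seed, size)
            mep_path = out / f"{cid}_mep.png"
            rdg_path = out / f"{cid}_rdg.png"
            Image.fromarray(mep).save(mep_path)
            Image.fromarray(rdg).save(rdg_path)
            rows.append(
                {
                    "id": cid,
                    "smiles": spec.smiles_pool[m],
                    "mep_path": str(mep_path),
                    "rdg_path": str(rdg_path),
                }
            )
            families[spec.family_id].append(cid)
            features[cid] = extractor.transform([rdg])[0]
    manifest = pd.DataFrame(rows)
    compounds = [Compound(**r) for r in rows]
    _check_thresholds(
        similarity_matrix(compounds), families, pos_thresh, neg_thresh
    )
    _check_glcm_separation(features, families)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
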
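"""Synthetic geometries and labels for end-to-end testing without downloads.

The generators produce idealized stand-ins for the real DFT-optimized
structures (which require an external quantum-chemistry stack): regular
polygons as topology oracles, calixarene-like four-ring macrocycle clouds in
each of the four conformations, and enthalpy labels that are an exact sparse
linear functional of the persistence-image pixels plus Gaussian noise.
Geometries use a fixed 1.40 Å aromatic bond length and planar rings;
realism is not the goal — exercising every code path deterministically is.
Every generator is fully reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .chemio import ManifestRow, MoleculePointCloud, write_manifest, write_xyz
from .imaging import ImageConfig, featurize_many
from .topology import TopoConfig

__all__ = [
    "ScaffoldAtomMap",
    "regular_polygon_cloud",
    "synthetic_calixarene",
    "synthetic_structure_set",
    "synthetic_labels",
    "write_fixture_set",
    "CONFORMATION_TILT_PATTERNS",
]

#: Per-conformation cyclic tilt-sign pattern of the four aryl rings.
CONFORMATION_TILT_PATTERNS = {
    "cone": (1, 1, 1, 1),
    "partial_cone": (1, 1, 1, -1),
    "alt12": (1, 1, -1, -1),
    "alt13": (1, -1, 1, -1),
}

RING_BOND = 1.40  # Å, idealized aromatic C-C
BRIDGE_SQUARE_SIDE = 5.0  # Å, bridge-atom square edge
RING_TILT = math.radians(45.0)  # aryl tilt out of the bridge plane
CHAIN_BOND = 1.50  # Å, substituent chain spacing
CO_BOND = 1.36  # Å, phenolic C-O


@dataclass
class ScaffoldAtomMap:
    """Indices of the conformation-defining atoms of a macrocycle cloud.

    ``rings`` lists, per aryl ring, its six atoms in cyclic order
    [C2, C3, C4, C5, C6, C1]: C2/C6 attach to the bridges, C4 is para,
    C1 bears the lower-rim oxygen.
    """

    bridge_atoms: tuple[int, int, int, int]
    rings: tuple[tuple[int, ...], ...]

    def para_atom(self, ring: int) -> int:
        return self.rings[ring][2]

    def attach_atoms(self, ring: int) -> tuple[int, int]:
        return self.rings[ring][0], self.rings[ring][4]

    def reindex(self, permutation: Sequence[int]) -> "ScaffoldAtomMap":
        """Map onto a cloud whose atom order was permuted (new = perm[old])."""
        p = list(permutation)
        return ScaffoldAtomMap(
            bridge_atoms=tuple(p[i] for i in self.bridge_atoms),
            rings=tuple(tuple(p[i] for i in ring) for ring in self.rings),
        )


def regular_polygon_cloud(n: int, side: float, element: str = "C") -> MoleculePointCloud:
    """n atoms at the vertices of a planar regular n-gon with the given side."""
    if n < 3:
        raise ValueError("polygon needs at least 3 vertices")
    if side <= 0:
        raise ValueError("side must be positive")
    radius = side / (2.0 * math.sin(math.pi / n))
    coords = [
        (radius * math.cos(2 * math.pi * k / n), radius * math.sin(2 * math.pi * k / n), 0.0)
        for k in range(n)
    ]
    return MoleculePointCloud(id=f"{element}{n}-ring", elements=(element,) * n, coords=np.array(coords))


def synthetic_calixarene(
    conformation: str,
    substituent_len: int = 0,
    noise: float = 0.0,
    seed: int = 0,
    structure_id: str | None = None,
    bridge_element: str = "C",
) -> tuple[MoleculePointCloud, ScaffoldAtomMap]:
    """Idealized calix[4]arene-like cloud in a chosen conformation.

    Four benzene-like hexagons sit on the edges of a square of bridge atoms,
    each tilted 45 degrees out of the bridge plane with the sign pattern of
    the requested conformation; a lower-rim oxygen hangs off every ring and
    an optional linear carbon chain extends from each para position.
    Gaussian coordinate noise (sd in Å) is applied last.
    """
    if conformation not in CONFORMATION_TILT_PATTERNS:
        raise ValueError(f"unknown conformation {conformation!r}")
    if noise < 0:
        raise ValueError("noise sd must be nonnegative")
    signs = CONFORMATION_TILT_PATTERNS[conformation]
    half = BRIDGE_SQUARE_SIDE / 2.0
    bridges = np.array(
        [[half, half, 0.0], [-half, half, 0.0], [-half, -half, 0.0], [half, -half, 0.0]]
    )
    normal = np.array([0.0, 0.0, 1.0])
    center = bridges.mean(axis=0)

    elements: list[str] = [bridge_element] * 4
    coords: list[np.ndarray] = list(bridges)
    rings: list[tuple[int, ...]] = []

    ring_radius = RING_BOND  # hexagon circumradius equals its side
    for k in range(4):
        b0, b1 = bridges[k], bridges[(k + 1) % 4]
        mid = (b0 + b1) / 2.0
        e = b1 - b0
        e = e / np.linalg.norm(e)
        out = mid - center
        out = out / np.linalg.norm(out)
        u = math.cos(RING_TILT) * out + signs[k] * math.sin(RING_TILT) * normal
        ring_center = mid + 1.8 * u
        # vertices at -90(C1), -30(C2), 30(C3), 90(C4), 150(C5), 210(C6)
        angles = {"C1": -90, "C2": -30, "C3": 30, "C4": 90, "C5": 150, "C6": 210}
        pos = {
            name: ring_center
            + ring_radius * (math.cos(math.radians(a)) * e + math.sin(math.radians(a)) * u)
            for name, a in angles.items()
        }
        start = len(elements)
        for name in ("C2", "C3", "C4", "C5", "C6", "C1"):
            elements.append("C")
            coords.append(pos[name])
        rings.append(tuple(range(start, start + 6)))
        # lower-rim oxygen below C1
        elements.append("O")
        coords.append(pos["C1"] - CO_BOND * u)
        # para substituent chain along the ring axis
        for j in range(substituent_len):
            elements.append("C")
            coords.append(pos["C4"] + (j + 1) * CHAIN_BOND * u)

    arr = np.array(coords)
    if noise > 0:
        rng = np.random.default_rng(seed)
        arr = arr + rng.normal(0.0, noise, size=arr.shape)
    sid = structure_id or f"synthetic-{conformation}-L{substituent_len}-s{seed}"
    cloud = MoleculePointCloud(id=sid, elements=tuple(elements), coords=arr)
    return cloud, ScaffoldAtomMap(bridge_atoms=(0, 1, 2, 3), rings=tuple(rings))


def synthetic_structure_set(
    n: int,
    seed: int = 0,
    noise: float = 0.02,
    conformations: Sequence[str] = tuple(CONFORMATION_TILT_PATTERNS),
    max_substituent_len: int = 3,
) -> tuple[list[MoleculePointCloud], list[ScaffoldAtomMap], list[ManifestRow]]:
    """A reproducible population of calixarene-like clouds.

    Conformation, substituent length and coordinate noise vary per structure
    so that both image channels and all four conformation labels are
    exercised.
    """
    rng = np.random.default_rng(seed)
    clouds, maps, rows = [], [], []
    for i in range(n):
        conf = conformations[int(rng.integers(len(conformations)))]
        slen = int(rng.integers(0, max_substituent_len + 1))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cloud, amap = synthetic_calixarene(
            conf, substituent_len=slen, noise=noise, seed=sub_seed,
            structure_id=f"synth-{i:04d}",
        )
        clouds.append(cloud)
        maps.append(amap)
        rows.append(
            ManifestRow(
                structure_id=cloud.id,
                family="calix",
                site="para" if slen else "none",
                substituent="C" * slen,
                conformation=conf,
            )
        )
    return clouds, maps, rows


def synthetic_labels(
    clouds: Sequence[MoleculePointCloud],
    n_weights: int = 20,
    label_sd: float = 2.5,
    intercept: float = -5.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    topo_config: TopoConfig = TopoConfig(),
    image_config: ImageConfig = ImageConfig(),
) -> tuple[np.ndarray, dict, np.ndarray]:
    """Labels linear in PI pixels: dH_i = w . PI(x_i) + b + N(0, noise_sd).

    The sparse weight vector lives on the ``n_weights`` highest-variance
    pixels of the generated descriptors and is rescaled so the noiseless
    labels have standard deviation ``label_sd`` (kcal/mol), mimicking the
    spread of computed adsorption enthalpies.  Returns (labels, ground truth
    record, descriptor matrix) so callers need not re-featurize.
    """
    rng = np.random.default_rng(seed)
    X = featurize_many(clouds, topo_config, image_config)
    variances = X.var(axis=0)
    support = np.argsort(variances)[::-1][:n_weights]
    support = np.sort(support)
    w_support = rng.normal(size=len(support))
    signal = X[:, support] @ w_support
    sd = signal.std()
    scale = label_sd / sd if sd > 0 else 0.0
    w_support = w_support * scale
    # center the pixel functional so labels sit at `intercept` on average;
    # the effective intercept is recorded so labels rebuild exactly from truth
    b_eff = intercept - scale * signal.mean()
    noiseless = X[:, support] @ w_support + b_eff
    labels = noiseless + rng.normal(0.0, noise_sd, size=len(clouds))
    truth = {
        "support": support.tolist(),
        "weights": w_support.tolist(),
        "intercept": b_eff,
        "noise_sd": noise_sd,
        "config_hash": image_config.config_hash(),
    }
    return labels, truth, X


def write_fixture_set(
    directory: str | Path,
    n: int,
    seed: int = 0,
    noise: float = 0.02,
    noise_sd: float = 0.3,
) -> None:
    """Write XYZ files, a labelled manifest and the label ground truth."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    clouds, _, rows = synthetic_structure_set(n, seed=seed, noise=noise)
    labels, truth, _ = synthetic_labels(clouds, noise_sd=noise_sd, seed=seed)
    for cloud, row, y in zip(clouds, rows, labels):
        write_xyz(cloud, directory / f"{cloud.id}.xyz")
        row.delta_h = float(y)
    write_manifest(rows, directory / "manifest.csv")
    (directory / "ground_truth.json").write_text(json.dumps(truth, indent=2), encoding="utf-8")
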
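"""Synthetic PSSM-like data with controllable interaction structure.

Real profile data needs PSI-BLAST and a large sequence database; this
module emulates its essential geometry offline so every pipeline stage
is testable.  Each protein's R x 20 matrix is a smooth low-frequency
field — a sum of low-order 2-D Legendre modes with random coefficients,
evaluated on the same cell-centered grid the descriptor uses — plus
white noise.  Because the latent structure lives in the Legendre basis,
the moment descriptor provably recovers it (the continuous moment of
mode (m, n) with coefficient c is exactly c), so classifier failures on
synthetic data cannot be blamed on the features.

Interaction structure: proteins come in small groups sharing a latent
coefficient vector drawn with scale delta (the class separation); each
group member perturbs it by sigma, and sigma-scaled white noise is added
to the matrix entries.  Positive pairs are drawn within groups, negative
pairs across groups, balanced 50/50.  With delta = 0 all groups share
the zero latent and the two classes are identically distributed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .legendre import legendre_poly
from .pssm import PSSM, write_pssm_file, write_pair_list

__all__ = ["SynthConfig", "SynthMeta", "make_synthetic_pssms", "make_labeled_pairs", "simulate_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    n_proteins: pool size (grouped into groups of group_size).
    length_range: inclusive [Rmin, Rmax] for sequence lengths.
    n_pairs: total labelled pairs (half positive, half negative).
    delta: class separation — scale of the group latent coefficients.
    sigma: noise scale — both the within-group coefficient jitter and
        the white noise added to matrix entries.
    latent_order: largest Legendre order (per axis) carrying signal.
    """

    n_proteins: int = 1500
    length_range: tuple[int, int] = (50, 150)
    n_pairs: int = 2000
    delta: float = 1.0
    sigma: float = 0.1
    seed: int = 0
    latent_order: int = 3
    group_size: int = 3

    def __post_init__(self) -> None:
        rmin, rmax = self.length_range
        if rmin < 1 or rmax < rmin:
            raise ValueError("length_range must satisfy 1 <= Rmin <= Rmax")
        if self.delta < 0 or self.sigma < 0:
            raise ValueError("need delta >= 0 and sigma >= 0")
        if self.n_pairs > self.n_proteins * (self.n_proteins - 1) // 2:
            raise ValueError("n_pairs exceeds the number of distinct pairs")
        if self.group_size < 2:
            raise ValueError("group_size must be >= 2")


@dataclass
class SynthMeta:
    """Ground truth of a generated pool: group ids and latent coefficients."""

    group_of: dict[str, int]
    coefficients: dict[str, np.ndarray] = field(repr=False)


def _mode_basis(n_cells: int, order: int) -> np.ndarray:
    """V_m at the cell centers of [-1, 1]: shape (n_cells, order + 1)."""
    x = -1.0 + (np.arange(n_cells) + 0.5) * 2.0 / n_cells
    return np.column_stack([legendre_poly(m, x) for m in range(order + 1)])


def make_synthetic_pssms(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[list[PSSM], SynthMeta]:
    """Generate the protein pool with group-structured latent fields.

    Protein i belongs to group i // group_size; its coefficient matrix
    is the group latent (N(0, delta^2) per mode) plus N(0, sigma^2)
    jitter, and the matrix adds N(0, sigma^2) white noise per entry.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    k = cfg.latent_order + 1
    n_groups = -(-cfg.n_proteins // cfg.group_size)
    latents = cfg.delta * rng.standard_normal((n_groups, k, k))
    width = len(str(cfg.n_proteins - 1))
    pssms, group_of, coeffs = [], {}, {}
    By = _mode_basis(20, cfg.latent_order)  # shared: 20 columns always
    for i in range(cfg.n_proteins):
        pid = f"syn{i:0{width}d}"
        g = i // cfg.group_size
        C = latents[g] + cfg.sigma * rng.standard_normal((k, k))
        R = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        Bx = _mode_basis(R, cfg.latent_order)
        mat = Bx @ C @ By.T + cfg.sigma * rng.standard_normal((R, 20))
        pssms.append(PSSM(protein_id=pid, matrix=mat))
        group_of[pid] = g
        coeffs[pid] = C
    return pssms, SynthMeta(group_of=group_of, coefficients=coeffs)


def make_labeled_pairs(
    meta: SynthMeta, cfg: SynthConfig, rng: np.random.Generator | None = None
) -> list[tuple[str, str, int]]:
    """Sample balanced labelled pairs: within-group +1, across-group -1.

    Sampling is without replacement over unordered pairs; a protein may
    appear in several pairs, as in real interaction data.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    ids = sorted(meta.group_of)
    n_pos = cfg.n_pairs // 2
    n_neg = cfg.n_pairs - n_pos
    by_group: dict[int, list[str]] = {}
    for pid in ids:
        by_group.setdefault(meta.group_of[pid], []).append(pid)
    within = [
        (a, b)
        for members in by_group.values()
        for i, a in enumerate(members)
        for b in members[i + 1:]
    ]
    if len(within) < n_pos:
        raise ValueError(
            f"insufficient proteins: only {len(within)} within-group pairs "
            f"available for {n_pos} positives"
        )
    pos_idx = rng.choice(len(within), size=n_pos, replace=False)
    positives = [within[i] for i in pos_idx]
    negatives: set[tuple[str, str]] = set()
    while len(negatives) < n_neg:
        a, b = rng.choice(len(ids), size=2, replace=False)
        pa, pb = ids[min(a, b)], ids[max(a, b)]
        if meta.group_of[pa] != meta.group_of[pb]:
            negatives.add((pa, pb))
    pairs = [(a, b, 1) for a, b in positives] + [(a, b, -1) for a, b in sorted(negatives)]
    perm = rng.permutation(len(pairs))
    return [pairs[i] for i in perm]


def simulate_dataset(
    cfg: SynthConfig, outdir: str | Path | None = None
) -> tuple[list[PSSM], list[tuple[str, str, int]], SynthMeta]:
    """Generate a full dataset; optionally write it to disk.

    When outdir is given, writes one PSI-BLAST-dialect file per protein
    under ``outdir/pssms/``, the pair list as ``pairs.tsv`` and a
    ``manifest.json`` recording the seed and parameters.  Output is
    byte-identical for identical configurations.
    """
    rng = np.random.default_rng(cfg.seed)
    pssms, meta = make_synthetic_pssms(cfg, rng)
    pairs = make_labeled_pairs(meta, cfg, rng)
    if outdir is not None:
        outdir = Path(outdir)
        pssm_dir = outdir / "pssms"
        pssm_dir.mkdir(parents=True, exist_ok=True)
        for p in pssms:
            write_pssm_file(p, pssm_dir / f"{p.protein_id}.pssm")
        write_pair_list(pairs, outdir / "pairs.tsv")
        manifest = {
            "generator": "ppilm.synthetic.simulate_dataset",
            "seed": cfg.seed,
            "n_proteins": cfg.n_proteins,
            "length_range": list(cfg.length_range),
            "n_pairs": cfg.n_pairs,
            "delta": cfg.delta,
            "sigma": cfg.sigma,
            "latent_order": cfg.latent_order,
            "group_size": cfg.group_size,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return pssms, pairs, meta
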
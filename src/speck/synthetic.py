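"""Synthetic paired scRNA-seq / ADT data with known ground truth.

The generator emulates the joint transcriptome/protein structure of a
CITE-seq experiment at desk scale: a low-rank log-mean drives background
gene expression through cell-type archetypes, receptor genes are bimodal
("on" in a subset of cell types, exactly off elsewhere) with extra dropout,
and a paired ADT readout is a noisy monotone transform of the true protein
level.  Everything is driven by one seeded generator, so a fixed seed
reproduces the data bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .evaluation import AdtMatrix
from .matrix_io import CountMatrix

__all__ = ["SyntheticTruth", "simulate_joint", "simulate_spectrum"]


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    cell_types: np.ndarray  # (m,) integer labels
    protein_level: np.ndarray  # (m, p) true surface protein; exactly 0 when off
    planted_rank: int
    receptor_genes: list[str]
    seed: int

    @property
    def on_mask(self) -> np.ndarray:
        """(m, p) boolean; True where the receptor is 'on' in that cell."""
        return self.protein_level > 0

    def to_dict(self) -> dict:
        return {
            "cell_types": self.cell_types.tolist(),
            "protein_level": self.protein_level.tolist(),
            "planted_rank": int(self.planted_rank),
            "receptor_genes": list(self.receptor_genes),
            "seed": int(self.seed),
        }


def simulate_joint(
    n_cells: int = 2000,
    n_genes: int = 300,
    n_receptors: int = 10,
    n_cell_types: int = 4,
    planted_rank: int = 8,
    dropout: float = 0.3,
    adt_noise: float = 0.35,
    seed: int = 0,
    dispersion: float | None = None,
    adt_background: float = 1.0,
    adt_gain: float = 100.0,
    rna_gain: float = 3.0,
) -> tuple[CountMatrix, AdtMatrix, SyntheticTruth]:
    """Simulate a paired count matrix, ADT matrix and ground truth.

    Background genes get Poisson (or negative binomial if ``dispersion`` is
    set) counts around ``exp`` of a rank-``planted_rank`` log-mean built
    from cell-type loadings.  Each receptor gene is "on" in a random proper
    subset of cell types; its transcript mean is proportional to the true
    protein level, and extra zeros are injected into "on" cells with
    probability ``dropout``.  ADT counts are
    ``Poisson(adt_gain * protein**0.7 * exp(N(0, adt_noise))) + adt_background``;
    the default ``adt_gain`` reflects the much deeper sequencing of antibody
    tags relative to transcripts, and the background is a constant ambient
    count.

    Parameters
    ----------
    dropout
        Probability in [0, 1) of forcing a receptor transcript count to
        zero in a cell where the receptor is on (capture failure).
    adt_noise
        Standard deviation of the multiplicative lognormal ADT noise.
    dispersion
        If given, counts are negative binomial with this size parameter
        (smaller = more overdispersed); default Poisson.
    """
    if n_receptors > n_genes:
        raise ValueError("n_receptors cannot exceed n_genes")
    if not 0 <= dropout < 1:
        raise ValueError(f"dropout must be in [0, 1), got {dropout}")
    if adt_noise <= 0:
        raise ValueError(f"adt_noise must be positive, got {adt_noise}")
    if planted_rank > min(n_cells, n_genes):
        raise ValueError("planted_rank cannot exceed min(n_cells, n_genes)")
    if n_cell_types < 1 or n_cell_types > n_cells:
        raise ValueError("invalid n_cell_types")
    rng = np.random.default_rng(seed)

    # balanced cell-type assignment, shuffled
    cell_types = np.arange(n_cells) % n_cell_types
    rng.shuffle(cell_types)

    # rank-limited log-mean for background genes via cell-type archetypes
    n_bg = n_genes - n_receptors
    arch = rng.normal(size=(n_cell_types, planted_rank))
    loadings = arch[cell_types] + 0.2 * rng.normal(size=(n_cells, planted_rank))
    gene_factors = rng.normal(size=(planted_rank, n_bg))
    L = loadings @ gene_factors
    L = L / max(L.std(), 1e-12)  # unit spread before exponentiation
    mu_bg = np.exp(-0.8 + 0.9 * L)

    # receptor genes: on/off by cell type, protein level lognormal within "on"
    protein = np.zeros((n_cells, n_receptors))
    mu_rc = np.zeros((n_cells, n_receptors))
    for j in range(n_receptors):
        if n_cell_types == 1:
            on_types = np.array([0])
        else:
            n_on = rng.integers(1, n_cell_types)  # proper subset: 1..T-1 types
            on_types = rng.choice(n_cell_types, size=n_on, replace=False)
        base = rng.uniform(2.0, 6.0, size=n_cell_types)
        on = np.isin(cell_types, on_types)
        protein[on, j] = base[cell_types[on]] * rng.lognormal(0.0, 0.5, size=on.sum())
        mu_rc[on, j] = rna_gain * protein[on, j]

    mu = np.empty((n_cells, n_genes))
    receptor_cols = rng.choice(n_genes, size=n_receptors, replace=False)
    receptor_cols.sort()
    bg_cols = np.setdiff1d(np.arange(n_genes), receptor_cols)
    mu[:, bg_cols] = mu_bg
    mu[:, receptor_cols] = mu_rc

    if dispersion is None:
        counts = rng.poisson(mu)
    else:
        # NB as gamma-Poisson mixture with shape = dispersion
        lam = rng.gamma(dispersion, mu / dispersion)
        counts = rng.poisson(lam)

    if dropout > 0:
        on_all = protein > 0
        drop = rng.random(size=on_all.shape) < dropout
        sub = counts[:, receptor_cols]
        sub[on_all & drop] = 0
        counts[:, receptor_cols] = sub

    gene_symbols = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    for r, col in enumerate(receptor_cols):
        gene_symbols[col] = f"RCPT{r + 1:02d}"
    barcodes = [f"CELL{i + 1:05d}" for i in range(n_cells)]

    # Poisson-sampled signal with multiplicative lognormal noise on top of a
    # constant ambient background count (so zero-protein cells tie exactly)
    lognoise = rng.normal(0.0, adt_noise, size=protein.shape)
    lam_adt = adt_gain * protein**0.7 * np.exp(lognoise)
    adt_counts = rng.poisson(lam_adt) + int(round(adt_background))

    count_matrix = CountMatrix(
        values=sp.csr_matrix(counts), gene_symbols=gene_symbols, cell_barcodes=barcodes
    )
    adt = AdtMatrix(
        values=adt_counts.astype(np.float64),
        antibody_names=[f"anti-RCPT{r + 1:02d}" for r in range(n_receptors)],
        cell_barcodes=list(barcodes),
        normalized=False,
    )
    truth = SyntheticTruth(
        cell_types=cell_types,
        protein_level=protein,
        planted_rank=planted_rank,
        receptor_genes=[f"RCPT{r + 1:02d}" for r in range(n_receptors)],
        seed=seed,
    )
    return count_matrix, adt, truth


def simulate_spectrum(
    planted_rank: int,
    n_components: int = 30,
    signal_gap: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Monotone-decreasing PC standard deviations with a known elbow.

    The consecutive drops before the elbow are large and pairwise distinct
    (after rounding to 2 decimals), the two drops at positions
    ``planted_rank - 1`` and ``planted_rank`` share the value
    ``round(signal_gap, 2)``, and later drops round to zero.  The plateau
    rule of :func:`speck.low_rank.rank_from_stdevs` therefore selects
    exactly ``planted_rank`` — unless ``signal_gap`` rounds below 0.01, in
    which case no run qualifies and the rule falls back to the full rank.
    """
    if planted_rank < 2:
        raise ValueError("planted_rank must be >= 2")
    if n_components <= planted_rank:
        raise ValueError("n_components must exceed planted_rank")
    rng = np.random.default_rng(seed)
    pr, R = planted_rank, n_components
    gap = round(float(signal_gap), 2)

    drops = np.empty(R - 1)
    # early drops: distinct multiples of 0.01 above the plateau value
    for i in range(pr - 2):
        drops[i] = gap + 0.03 * (pr - 2 - i) + rng.uniform(-0.0019, 0.0019)
    # the qualifying run: two consecutive drops with the same rounded value
    drops[pr - 2] = gap + rng.uniform(-0.0019, 0.0019)
    drops[pr - 1] = gap + rng.uniform(-0.0019, 0.0019)
    # tail: below rounding resolution
    drops[pr:] = rng.uniform(0.0, 0.004, size=R - 1 - pr)
    np.maximum(drops, 0.0, out=drops)  # keep stdevs monotone even for gap ~ 0

    stdevs = np.empty(R)
    stdevs[-1] = 0.5
    for i in range(R - 2, -1, -1):
        stdevs[i] = stdevs[i + 1] + drops[i]
    return stdevs
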
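"""Synthetic enzyme-network studies with correlated heterogeneous gene data.

A shared low-dimensional latent vector per gene drives everything: the
interaction graph (edge probability decays with latent distance through a
logistic link), the numeric expression table, the binary localization and
phylogenetic tables (noisy thresholded linear maps), and the protein
sequences (latent clusters carry planted signature motifs, so interacting
genes tend to share n-grams).  Because all channels are noisy views of the
same latent geometry, every gene kernel is genuinely informative about
edges, the channels are complementary, and the full pipeline is testable
end-to-end without any external download.

Dimensions default to the shapes of the classic yeast compendium: 157
expression experiments, 23 intracellular localizations, 145 organisms in
the phylogenetic profile.

Everything is bit-reproducible: each stage draws from its own
``numpy.random.Generator`` seeded from (seed, stage tag).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit
from sklearn.cluster import KMeans

from .kernels import (FeatureTable, KernelError, KernelMatrix, MotifSet,
                      SequenceSet, STANDARD_AA, feature_log_e_kernel,
                      linear_kernel, motif_kernel, motif_match_counts,
                      normalize_kernel, rbf_kernel, spectrum_kernel)
from .network import InteractionNetwork, PairDataset

_STAGE = {"network": 1, "features": 2, "sequences": 3, "permute": 4}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STAGE[stage]])


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings for the default study conditions."""

    n_genes: int = 120
    latent_dim: int = 6
    edge_density: float = 0.06
    distance_coef: float = 4.0   # logistic slope on latent distance; 0 = Erdos-Renyi
    noise_sd: float = 0.8
    channel_view_dims: int = 4   # latent dims visible to each non-sequence channel
    expression_dim: int = 157
    localization_dim: int = 23
    phylo_dim: int = 145
    seq_len: tuple[int, int] = (60, 120)
    n_motifs: int = 8
    motif_len: tuple[int, int] = (4, 6)
    insertions_per_carrier: int = 2
    insertion_rate: float = 0.8
    log_e_strength: float = 4.0
    seed: int = 0


@dataclass(frozen=True)
class SyntheticStudy:
    network: InteractionNetwork
    latent: np.ndarray
    expression: FeatureTable
    localization: FeatureTable
    phylo: FeatureTable
    sequences: SequenceSet
    motifs: MotifSet
    log_e: FeatureTable
    params: SyntheticParams

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return self.expression.gene_ids


def _gene_ids(n: int) -> tuple[str, ...]:
    width = max(3, len(str(n - 1)))
    return tuple(f"g{i:0{width}d}" for i in range(n))


def generate_network(n_genes: int, latent_dim: int, edge_density: float,
                     seed: int, distance_coef: float = 2.0
                     ) -> tuple[InteractionNetwork, np.ndarray]:
    """Latent-space random graph with calibrated expected density.

    Edge (i, j) is present with probability logistic(a - b ||z_i - z_j||);
    the intercept a is calibrated by bisection so the mean edge probability
    equals ``edge_density``.  ``distance_coef`` = 0 degenerates to an
    Erdos-Renyi graph.
    """
    if n_genes < 4:
        raise KernelError("need at least 4 genes")
    if not 0.0 < edge_density < 1.0:
        raise KernelError(f"edge density {edge_density} outside (0, 1)")
    rng = _rng(seed, "network")
    z = rng.standard_normal((n_genes, latent_dim))
    dist = pdist(z)

    def mean_p(a: float) -> float:
        return float(expit(a - distance_coef * dist).mean())

    lo, hi = -60.0, 60.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if mean_p(mid) < edge_density:
            lo = mid
        else:
            hi = mid
    a = (lo + hi) / 2.0
    p = expit(a - distance_coef * squareform(dist))
    ids = _gene_ids(n_genes)
    u = rng.random((n_genes, n_genes))
    edges = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if u[i, j] < p[i, j]:
                edges.append((ids[i], ids[j]))
    net = InteractionNetwork.from_edges(edges, extra_vertices=ids)
    return net, z


def _channel_view(latent: np.ndarray, channel: int, view_dims: int) -> np.ndarray:
    """Rotating subset of latent dimensions visible to one data channel.

    Channel c sees dims (2c, 2c+1, ..., 2c+view_dims-1) modulo latent_dim,
    so different channels carry overlapping but distinct slices of the
    latent geometry -- this is what makes the channels complementary and
    lets the weighted kernel combination beat every single kernel."""
    d = latent.shape[1]
    if view_dims >= d:
        return latent
    idx = [(2 * channel + j) % d for j in range(view_dims)]
    return latent[:, idx]


def generate_features(latent: np.ndarray,
                      dims: tuple[int, int, int] = (157, 23, 145),
                      noise_sd: float = 0.5, seed: int = 0,
                      gene_ids: tuple[str, ...] | None = None,
                      view_dims: int = 4
                      ) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """Expression (numeric), localization and phylogenetic (binary) tables
    as noisy linear / thresholded-linear maps of channel-specific views of
    the latent vectors."""
    if noise_sd < 0:
        raise KernelError("noise_sd must be nonnegative")
    n = latent.shape[0]
    ids = gene_ids or _gene_ids(n)
    rng = _rng(seed, "features")
    d_exp, d_loc, d_phy = dims
    out = []
    for channel, (d_out, kind) in enumerate(
            [(d_exp, "expression"), (d_loc, "localization"),
             (d_phy, "phylogenetic")]):
        view = _channel_view(latent, channel, view_dims)
        W = rng.standard_normal((view.shape[1], d_out)) / np.sqrt(view.shape[1])
        raw = view @ W + noise_sd * rng.standard_normal((n, d_out))
        values = raw if kind == "expression" else (raw > 0.0).astype(float)
        out.append(FeatureTable(ids, values, kind))
    return tuple(out)


def generate_sequences(latent: np.ndarray, seq_len: tuple[int, int] = (60, 120),
                       n_motifs: int = 8, insertion_rate: float = 0.8,
                       seed: int = 0,
                       motif_len: tuple[int, int] = (4, 6),
                       insertions_per_carrier: int = 2,
                       log_e_strength: float = 4.0,
                       gene_ids: tuple[str, ...] | None = None
                       ) -> tuple[SequenceSet, MotifSet, FeatureTable]:
    """Random protein sequences with cluster-specific planted motifs.

    Genes are k-means-clustered in latent space (k = n_motifs); each cluster
    owns a signature motif inserted into each carrier gene's sequence
    ``insertions_per_carrier`` times with probability ``insertion_rate``.
    The log-E table holds noisy per-gene motif-hit strengths (a desk-scale
    stand-in for profile-HMM domain scores).
    """
    if n_motifs < 1:
        raise KernelError("need at least one motif")
    if not 0.0 <= insertion_rate <= 1.0:
        raise KernelError("insertion_rate must be in [0, 1]")
    n = latent.shape[0]
    ids = gene_ids or _gene_ids(n)
    rng = _rng(seed, "sequences")
    lo, hi = seq_len
    if lo > hi or lo < max(motif_len):
        raise KernelError("sequence length range shorter than the motifs")
    aa = np.array(list(STANDARD_AA))
    km = KMeans(n_clusters=min(n_motifs, n), n_init=10,
                random_state=int(np.random.default_rng([seed, 30]).integers(2 ** 31)))
    clusters = km.fit_predict(latent)
    motifs: list[str] = []
    while len(motifs) < n_motifs:
        L = int(rng.integers(motif_len[0], motif_len[1] + 1))
        m = "".join(rng.choice(aa, size=L))
        if m not in motifs:
            motifs.append(m)
    seqs = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        s = list(rng.choice(aa, size=L))
        if rng.random() < insertion_rate:
            motif = motifs[clusters[i] % n_motifs]
            for _ in range(insertions_per_carrier):
                pos = int(rng.integers(0, L - len(motif) + 1))
                s[pos:pos + len(motif)] = list(motif)
        seqs.append("".join(s))
    seq_set = SequenceSet(ids, tuple(seqs))
    motif_set = MotifSet(tuple(motifs))
    hits = motif_match_counts(seq_set, motif_set)
    log_e = np.maximum(
        0.0, log_e_strength * hits + rng.standard_normal(hits.shape))
    return seq_set, motif_set, FeatureTable(ids, log_e, "log_e")


def generate_study(params: SyntheticParams | None = None, **overrides
                   ) -> SyntheticStudy:
    """Generate a complete synthetic study (graph + all data channels)."""
    params = replace(params or SyntheticParams(), **overrides)
    net, z = generate_network(params.n_genes, params.latent_dim,
                              params.edge_density, params.seed,
                              params.distance_coef)
    ids = _gene_ids(params.n_genes)
    expr, loc, phy = generate_features(
        z, (params.expression_dim, params.localization_dim, params.phylo_dim),
        params.noise_sd, params.seed, ids, params.channel_view_dims)
    seqs, motifs, log_e = generate_sequences(
        z, params.seq_len, params.n_motifs, params.insertion_rate,
        params.seed, params.motif_len, params.insertions_per_carrier,
        params.log_e_strength, ids)
    return SyntheticStudy(net, z, expr, loc, phy, seqs, motifs, log_e, params)


def build_study_kernels(study: SyntheticStudy,
                        normalize: bool = True) -> dict[str, KernelMatrix]:
    """The six gene-level kernels of a study, cosine-normalized by default."""
    kernels = {
        "k_exp": rbf_kernel(study.expression, name="k_exp"),
        "k_loc": linear_kernel(study.localization, name="k_loc"),
        "k_phy": rbf_kernel(study.phylo, name="k_phy"),
        "k_pfam": feature_log_e_kernel(study.log_e, name="k_pfam"),
        "k_motif": motif_kernel(study.sequences, study.motifs, name="k_motif"),
        "k_ngram": spectrum_kernel(study.sequences, n=3, name="k_ngram"),
    }
    if normalize:
        for nm in list(kernels):
            K = kernels[nm]
            d = np.diag(K.values)
            if (d <= 0).any():  # genes with no motif hits / short sequences
                eps = max(1e-12, 1e-12 * np.abs(K.values).max())
                K = KernelMatrix(K.gene_ids, K.values + eps * np.eye(K.n_genes),
                                 K.name)
            kernels[nm] = normalize_kernel(K)
    return kernels


def permute_labels(data: PairDataset, seed: int) -> PairDataset:
    """Null control: uniformly permute labels, leaving the pairs untouched."""
    if len(data) == 0:
        raise KernelError("empty dataset")
    rng = _rng(seed, "permute")
    perm = rng.permutation(len(data))
    return PairDataset(data.pairs, data.labels[perm], seed)
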
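"""Gene-level kernels over heterogeneous genomic data.

Six kernels are supported, mirroring the data channels commonly used for
enzyme network inference in yeast:

* ``k_exp``   -- Gaussian RBF kernel on numeric expression profiles,
* ``k_loc``   -- linear kernel on binary intracellular-localization vectors,
* ``k_phy``   -- Gaussian RBF kernel on binary phylogenetic profiles,
* ``k_pfam``  -- dot-product kernel on transformed (-log10) domain E-values,
* ``k_motif`` -- dot-product kernel on discrete-motif match counts,
* ``k_ngram`` -- spectrum kernel on overlapping n-gram (k-mer) counts.

All builders return :class:`KernelMatrix` objects, which carry the gene id
ordering alongside the Gram matrix and enforce symmetry.  Kernels are made
commensurable for weighted sums via :func:`normalize_kernel` (cosine
normalization) and can be validated or repaired with :func:`assert_psd`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.spatial.distance import pdist, squareform

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(STANDARD_AA)

FEATURE_KINDS = ("expression", "localization", "phylogenetic", "log_e")
_BINARY_KINDS = ("localization", "phylogenetic")

SYMMETRY_TOL = 1e-10
PSD_RTOL = 1e-8


class KernelError(ValueError):
    """Raised on invalid kernel inputs (bad parameters, mismatched ids...)."""


def _check_unique_ids(gene_ids: Sequence[str]) -> tuple[str, ...]:
    ids = tuple(str(g) for g in gene_ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise KernelError(f"duplicate gene ids: {dupes}")
    if not ids:
        raise KernelError("empty gene id list")
    return ids


@dataclass(frozen=True)
class FeatureTable:
    """Per-gene fixed-dimension feature vectors.

    ``kind`` tags the data channel; binary channels (localization,
    phylogenetic) are checked to contain only {0, 1}.
    """

    gene_ids: tuple[str, ...]
    values: np.ndarray
    kind: str

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", _check_unique_ids(self.gene_ids))
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise KernelError("feature table must be 2-D (genes x features)")
        if values.shape[0] != len(self.gene_ids):
            raise KernelError(
                f"{values.shape[0]} rows for {len(self.gene_ids)} gene ids"
            )
        if self.kind not in FEATURE_KINDS:
            raise KernelError(f"unknown feature kind {self.kind!r}")
        if self.kind in _BINARY_KINDS and not np.isin(values, (0.0, 1.0)).all():
            raise KernelError(f"{self.kind} table must be binary (0/1)")
        object.__setattr__(self, "values", values)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SequenceSet:
    """Named protein sequences over the 20-letter amino-acid alphabet
    (ambiguity codes X/B/Z/U/O and ``*`` are tolerated but never matched)."""

    gene_ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", _check_unique_ids(self.gene_ids))
        seqs = tuple(str(s).upper() for s in self.sequences)
        if len(seqs) != len(self.gene_ids):
            raise KernelError("sequence count does not match gene id count")
        for g, s in zip(self.gene_ids, seqs):
            if not s:
                raise KernelError(f"empty sequence for gene {g}")
        object.__setattr__(self, "sequences", seqs)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


_MOTIF_TOKEN = re.compile(rf"\[([{STANDARD_AA}]+)\]|([{STANDARD_AA}])|(\.)")


def _parse_motif(pattern: str) -> str:
    """Translate an eMotif-like pattern into an anchored regex.

    Supported syntax: literal residues, bracketed residue classes such as
    ``[AG]``, and ``.`` as a single-position wildcard over the 20 standard
    amino acids.  Ambiguity codes never match.
    """
    if not pattern:
        raise KernelError("empty motif pattern")
    pos = 0
    out = []
    for tok in _MOTIF_TOKEN.finditer(pattern):
        if tok.start() != pos:
            raise KernelError(f"malformed motif pattern {pattern!r} at position {pos}")
        cls, lit, dot = tok.groups()
        if cls is not None:
            out.append(f"[{cls}]")
        elif lit is not None:
            out.append(lit)
        else:
            out.append(f"[{STANDARD_AA}]")
        pos = tok.end()
    if pos != len(pattern):
        raise KernelError(f"malformed motif pattern {pattern!r} at position {pos}")
    return "".join(out)


@dataclass(frozen=True)
class MotifSet:
    """Discrete sequence motifs (literal / [class] / '.' wildcard syntax)."""

    motifs: tuple[str, ...]

    def __post_init__(self):
        motifs = tuple(str(m) for m in self.motifs)
        if not motifs:
            raise KernelError("motif set is empty")
        for m in motifs:
            _parse_motif(m)  # raises on malformed patterns
        object.__setattr__(self, "motifs", motifs)

    def __len__(self) -> int:
        return len(self.motifs)


@dataclass
class KernelMatrix:
    """A named symmetric similarity (Gram) matrix over an ordered gene set."""

    gene_ids: tuple[str, ...]
    values: np.ndarray
    name: str = "kernel"
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.gene_ids = _check_unique_ids(self.gene_ids)
        values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if values.shape != (n, n):
            raise KernelError(f"kernel shape {values.shape} for {n} genes")
        asym = np.abs(values - values.T).max() if n else 0.0
        if asym > max(SYMMETRY_TOL, SYMMETRY_TOL * np.abs(values).max()):
            raise KernelError(f"kernel {self.name!r} asymmetric (max dev {asym:.3g})")
        self.values = (values + values.T) / 2.0
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KernelError(f"unknown gene id {gene!r} in kernel {self.name!r}") from None

    def indices(self, genes: Iterable[str]) -> np.ndarray:
        return np.array([self.index(g) for g in genes], dtype=int)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])


def median_bandwidth(features: FeatureTable) -> float:
    """Median heuristic for the RBF bandwidth: the median nonzero pairwise
    Euclidean distance between feature rows."""
    d = pdist(features.values)
    d = d[d > 0]
    if d.size == 0:
        raise KernelError("all feature rows identical; cannot infer a bandwidth")
    return float(np.median(d))


def rbf_kernel(features: FeatureTable, sigma: float | None = None,
               name: str = "k_rbf") -> KernelMatrix:
    """Gaussian RBF kernel K_ij = exp(-||x_i - x_j||^2 / (2 sigma^2)).

    With ``sigma=None`` the median heuristic bandwidth is used.
    """
    if sigma is None:
        sigma = median_bandwidth(features)
    sigma = float(sigma)
    if not sigma > 0:
        raise KernelError(f"RBF bandwidth must be positive, got {sigma}")
    d2 = squareform(pdist(features.values, metric="sqeuclidean"))
    K = np.exp(-d2 / (2.0 * sigma * sigma))
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(features.gene_ids, K, name)


def linear_kernel(features: FeatureTable, name: str = "k_linear") -> KernelMatrix:
    """Linear kernel K_ij = x_i . x_j."""
    X = features.values
    return KernelMatrix(features.gene_ids, X @ X.T, name)


def _ngram_counts(seq: str, n: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - n + 1):
        g = seq[i:i + n]
        if all(c in _AA_SET for c in g):
            counts[g] = counts.get(g, 0) + 1
    return counts


def spectrum_kernel(seqs: SequenceSet, n: int = 3,
                    name: str = "k_ngram") -> KernelMatrix:
    """Spectrum (n-gram) kernel: dot products of overlapping n-gram count
    vectors.  n-grams containing non-standard residues are skipped; sequences
    shorter than ``n`` have an all-zero feature vector."""
    if n < 1:
        raise KernelError(f"n-gram length must be >= 1, got {n}")
    vocab: dict[str, int] = {}
    rows, cols, data = [], [], []
    for i, seq in enumerate(seqs.sequences):
        for g, c in _ngram_counts(seq, n).items():
            j = vocab.setdefault(g, len(vocab))
            rows.append(i)
            cols.append(j)
            data.append(c)
    m = len(seqs.gene_ids)
    X = csr_matrix((data, (rows, cols)), shape=(m, max(len(vocab), 1)), dtype=float)
    K = (X @ X.T).toarray()
    return KernelMatrix(seqs.gene_ids, K, name)


def motif_match_counts(seqs: SequenceSet, motifs: MotifSet) -> np.ndarray:
    """Matrix of overlapping match counts, genes x motifs.

    Matches are counted at every start position (overlaps allowed)."""
    patterns = [re.compile(f"(?=(?:{_parse_motif(m)}))") for m in motifs.motifs]
    V = np.zeros((seqs.n_genes, len(motifs)), dtype=float)
    for i, seq in enumerate(seqs.sequences):
        for j, pat in enumerate(patterns):
            V[i, j] = sum(1 for _ in pat.finditer(seq))
    return V


def motif_kernel(seqs: SequenceSet, motifs: MotifSet,
                 name: str = "k_motif") -> KernelMatrix:
    """Motif kernel: dot products of per-gene motif match-count vectors."""
    V = motif_match_counts(seqs, motifs)
    return KernelMatrix(seqs.gene_ids, V @ V.T, name)


def transform_e_values(e_values: np.ndarray, floor: float = 1e-300) -> np.ndarray:
    """Map raw E-values to nonnegative features: max(0, -log10 E).

    Smaller E-values (stronger hits) give larger features; E >= 1 (and absent
    hits coded as E = 1 or larger) map to 0."""
    e = np.clip(np.asarray(e_values, dtype=float), floor, None)
    return np.maximum(0.0, -np.log10(e))


def feature_log_e_kernel(table: FeatureTable, name: str = "k_pfam",
                         tol: float = 1e-9) -> KernelMatrix:
    """Dot-product kernel on transformed E-value vectors (Pfam-style).

    ``table`` must hold already-transformed, nonnegative log-E features
    (see :func:`transform_e_values`)."""
    if table.kind != "log_e":
        raise KernelError(f"expected a log_e feature table, got kind {table.kind!r}")
    if table.values.min() < -tol:
        raise KernelError("log-E features must be nonnegative after transform")
    X = np.maximum(table.values, 0.0)
    return KernelMatrix(table.gene_ids, X @ X.T, name)


def normalize_kernel(K: KernelMatrix) -> KernelMatrix:
    """Cosine-normalize: K'_ij = K_ij / sqrt(K_ii K_jj); unit diagonal.

    Genes with nonpositive self-similarity are an error (named in the
    message) -- they carry no feature mass to normalize by."""
    d = np.diag(K.values).copy()
    bad = np.where(d <= 0)[0]
    if bad.size:
        raise KernelError(
            f"cannot normalize kernel {K.name!r}: nonpositive diagonal for "
            f"gene(s) {[K.gene_ids[i] for i in bad[:5]]}"
        )
    s = 1.0 / np.sqrt(d)
    Kn = K.values * np.outer(s, s)
    np.fill_diagonal(Kn, 1.0)
    return KernelMatrix(K.gene_ids, Kn, K.name)


def assert_psd(K: KernelMatrix, tol: float = PSD_RTOL) -> tuple[KernelMatrix, str]:
    """Validate positive semidefiniteness; clip negative eigenvalues if needed.

    Returns ``(kernel, diagnostic)`` with diagnostic ``"psd"`` when the
    minimum eigenvalue is >= -tol * max eigenvalue, else ``"repaired"`` and
    the nearest-PSD reconstruction (negative eigenvalues set to zero).
    """
    if tol < 0:
        raise KernelError("PSD tolerance must be nonnegative")
    w, V = np.linalg.eigh(K.values)
    scale = max(w.max(), 0.0)
    if w.min() >= -tol * max(scale, np.finfo(float).tiny):
        return K, "psd"
    w_clipped = np.clip(w, 0.0, None)
    repaired = (V * w_clipped) @ V.T
    repaired = (repaired + repaired.T) / 2.0
    return KernelMatrix(K.gene_ids, repaired, K.name), "repaired"


def min_eig_ratio(values: np.ndarray) -> float:
    """min eigenvalue / max eigenvalue of a symmetric matrix (test helper)."""
    w = np.linalg.eigvalsh((values + values.T) / 2.0)
    return float(w.min() / max(w.max(), np.finfo(float).tiny))
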
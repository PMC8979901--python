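"""Pedigree, genomic and combined relationship matrices.

Implements the numerator relationship matrix **A** (tabular method) and its
direct inverse (Henderson's rules with inbreeding), the realized genomic
relationship **G** (VanRaden method 1), the blended G, the single-step
combined matrix **H** in the three representations the animal model needs
(H, its inverse, and a Cholesky factor), PCA of a GRM, and pairwise LD as
the squared dosage correlation.

The combined matrix follows the standard single-step construction

    H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1]

with the correction placed on the genotyped block of the pedigree, and the
explicit block form of H used for the Cholesky-transformed model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import GenotypeMatrix, Pedigree

logger = logging.getLogger("ssgeval.relmat")

KINDS = ("A", "A_inverse", "A22", "G", "H", "H_inverse", "H_cholesky")


@dataclass
class RelationshipMatrix:
    """A (possibly factored) relationship matrix with its animal index."""

    kind: str
    index: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind '{self.kind}'")
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.index)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} animals"
            )

    def __len__(self) -> int:
        return len(self.index)

    def submatrix(self, animal_ids: Sequence[str]) -> "RelationshipMatrix":
        pos = {a: i for i, a in enumerate(self.index)}
        idx = np.array([pos[a] for a in animal_ids])
        return RelationshipMatrix(
            self.kind,
            list(animal_ids),
            self.values[np.ix_(idx, idx)],
            dict(self.meta),
        )

    # -- serialization ------------------------------------------------------

    def to_sparse_text(self, path, tol: float = 0.0) -> None:
        """Write the upper triangle as ``id_i<TAB>id_j<TAB>value`` lines."""
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind}\n")
            iu, ju = np.triu_indices(len(self))
            v = self.values[iu, ju]
            keep = np.abs(v) > tol if tol > 0 else slice(None)
            for i, j, x in zip(iu[keep], ju[keep], v[keep]):
                fh.write(f"{self.index[i]}\t{self.index[j]}\t{x:.12g}\n")

    @classmethod
    def from_sparse_text(cls, path, index: Sequence[str] | None = None):
        kind = "A"
        entries = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if "kind=" in line:
                        kind = line.split("kind=")[1].strip()
                    continue
                a, b, v = line.rstrip("\n").split("\t")
                entries.append((a, b, float(v)))
        if index is None:
            seen: list[str] = []
            known: set[str] = set()
            for a, b, _ in entries:
                for x in (a, b):
                    if x not in known:
                        known.add(x)
                        seen.append(x)
            index = seen
        pos = {a: i for i, a in enumerate(index)}
        vals = np.zeros((len(index), len(index)))
        for a, b, v in entries:
            vals[pos[a], pos[b]] = v
            vals[pos[b], pos[a]] = v
        return cls(kind, list(index), vals)


# ---------------------------------------------------------------------------
# Pedigree relationships
# ---------------------------------------------------------------------------


def numerator_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Tabular-method **A**: expected additive relatedness from the pedigree.

    ``a(i,i) = 1 + a(s,d)/2`` and ``a(i,j) = (a(j,s) + a(j,d))/2`` for
    earlier-born ``j``; unknown parents contribute zero.
    """
    n = len(ped)
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix("A", list(ped.ids), A)


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """F per animal (diagonal of A minus one)."""
    return np.diag(numerator_relationship(ped).values) - 1.0


def a_inverse(ped: Pedigree) -> RelationshipMatrix:
    """Direct inverse of **A** by Henderson's rules, with inbreeding.

    The Mendelian-sampling variance of animal ``i`` is
    ``d_i = 0.5 - 0.25 (F_s + F_d)`` (0.75 - 0.25 F_p with one known
    parent, 1 with none), using inbreeding coefficients from the tabular
    diagonal.  The result is sparse in structure — nonzeros arise only
    within parent-offspring triplets.
    """
    n = len(ped)
    F = inbreeding_coefficients(ped)
    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            di = 0.75 - 0.25 * F[p]
        else:
            di = 1.0
        alpha = 1.0 / di
        Ainv[i, i] += alpha
        for p in (s, d):
            if p >= 0:
                Ainv[i, p] -= alpha / 2
                Ainv[p, i] -= alpha / 2
                Ainv[p, p] += alpha / 4
        if s >= 0 and d >= 0:
            Ainv[s, d] += alpha / 4
            Ainv[d, s] += alpha / 4
    return RelationshipMatrix("A_inverse", list(ped.ids), Ainv)


def a22(
    ped: Pedigree,
    genotyped_ids: Sequence[str],
    A: RelationshipMatrix | None = None,
) -> RelationshipMatrix:
    """Sub-block of **A** for the genotyped animals, in pedigree order.

    Pass a precomputed ``A`` to avoid rebuilding it.
    """
    ordered = [a for a in ped.ids if a in set(genotyped_ids)]
    if A is None:
        A = numerator_relationship(ped)
    out = A.submatrix(ordered)
    out.kind = "A22"
    return out


# ---------------------------------------------------------------------------
# Genomic relationships
# ---------------------------------------------------------------------------


def genomic_relationship(
    G: GenotypeMatrix, freq_source: str = "observed", freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """VanRaden method-1 GRM: ``ZZ' / (2 sum p(1-p))`` with 2p-centred calls.

    Requires a complete (imputed) call matrix; monomorphic markers are an
    error — they contribute nothing to the denominator and should have
    been removed by QC.
    """
    calls = G.calls
    if (calls < 0).any():
        raise ValueError("missing calls present; run impute_missing first")
    if freq_source == "observed":
        p = calls.mean(axis=0) / 2.0
    elif freq_source == "supplied":
        if freqs is None:
            raise ValueError("freq_source='supplied' needs freqs")
        p = np.asarray(freqs, dtype=np.float64)
    else:
        raise ValueError(f"unknown freq_source '{freq_source}'")
    if ((p <= 0) | (p >= 1)).any():
        bad = G.markers.loc[(p <= 0) | (p >= 1), "snp_id"].tolist()
        raise ValueError(f"monomorphic markers in GRM input: {bad[:5]}")
    Z = calls.astype(np.float64) - 2.0 * p
    denom = 2.0 * float((p * (1 - p)).sum())
    vals = (Z @ Z.T) / denom
    return RelationshipMatrix(
        "G",
        list(G.animal_ids),
        vals,
        meta={"freq_source": freq_source, "n_markers": G.n_markers},
    )


def blend_g(
    Graw: RelationshipMatrix, A22m: RelationshipMatrix, weight: float = 0.95
) -> RelationshipMatrix:
    """``G* = w G + (1-w) A22`` — guarantees invertibility for w < 1."""
    if not (0 < weight <= 1):
        raise ValueError("blend weight must lie in (0, 1]")
    if Graw.index != A22m.index:
        raise ValueError("G and A22 must be indexed by the same animals")
    vals = weight * Graw.values + (1 - weight) * A22m.values
    meta = dict(Graw.meta)
    meta["blend_weight"] = weight
    return RelationshipMatrix("G", list(Graw.index), vals, meta)


# ---------------------------------------------------------------------------
# Single-step combined matrix
# ---------------------------------------------------------------------------


def h_inverse(
    Ainv: RelationshipMatrix,
    Ginv: RelationshipMatrix,
    A22inv: RelationshipMatrix,
    genotyped_index: Sequence[str],
) -> RelationshipMatrix:
    """``H^-1 = A^-1 + blockdiag(0, G^-1 - A22^-1)`` on the genotyped block."""
    if Ginv.index != list(genotyped_index) or A22inv.index != list(genotyped_index):
        raise ValueError("G^-1 and A22^-1 must be indexed by the genotyped subset")
    pos = {a: i for i, a in enumerate(Ainv.index)}
    missing = [a for a in genotyped_index if a not in pos]
    if missing:
        raise ValueError(f"genotyped animals not in pedigree index: {missing[:5]}")
    gi = np.array([pos[a] for a in genotyped_index], dtype=np.int64)
    vals = Ainv.values.copy()
    if len(gi):
        vals[np.ix_(gi, gi)] += Ginv.values - A22inv.values
    return RelationshipMatrix("H_inverse", list(Ainv.index), vals)


def h_matrix(
    A: RelationshipMatrix,
    G: RelationshipMatrix,
    genotyped_index: Sequence[str],
    jitter: float = 1e-8,
) -> tuple[RelationshipMatrix, RelationshipMatrix]:
    """Assemble **H** explicitly and factor it.

    Block form (1 = non-genotyped, 2 = genotyped):

    * ``H11 = A11 + A12 A22^-1 (G - A22) A22^-1 A21``
    * ``H12 = A12 A22^-1 G``
    * ``H22 = G``

    Returns ``(H, L)`` with ``L`` lower-triangular, ``L L' = H``.  If the
    plain Cholesky fails, ``jitter * I`` is added once (logged); failure
    after that raises, reporting the minimum eigenvalue.
    """
    pos = {a: i for i, a in enumerate(A.index)}
    gi = np.array([pos[a] for a in genotyped_index])
    ni = np.array([i for i in range(len(A)) if i not in set(gi.tolist())])
    Av = A.values
    Gv = G.values
    A22v = Av[np.ix_(gi, gi)]
    A22inv = np.linalg.inv(A22v)
    H = Av.copy()
    if len(gi):
        H[np.ix_(gi, gi)] = Gv
        if len(ni):
            A12 = Av[np.ix_(ni, gi)]
            B = A12 @ A22inv  # n1 x n2
            H[np.ix_(ni, gi)] = B @ Gv
            H[np.ix_(gi, ni)] = (B @ Gv).T
            H[np.ix_(ni, ni)] = (
                Av[np.ix_(ni, ni)] + B @ (Gv - A22v) @ B.T
            )
    jittered = False
    try:
        L = np.linalg.cholesky(H)
    except np.linalg.LinAlgError:
        logger.warning("Cholesky of H failed; adding jitter %.1e to the diagonal", jitter)
        jittered = True
        try:
            L = np.linalg.cholesky(H + jitter * np.eye(len(H)))
        except np.linalg.LinAlgError as e:
            lam_min = float(np.linalg.eigvalsh(H)[0])
            raise np.linalg.LinAlgError(
                f"H is not positive definite even after jitter "
                f"(min eigenvalue {lam_min:.3e}); blend G before assembling H"
            ) from e
    meta = {"jitter": jitter if jittered else 0.0}
    return (
        RelationshipMatrix("H", list(A.index), H, meta),
        RelationshipMatrix("H_cholesky", list(A.index), L, meta),
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def grm_pca(G: RelationshipMatrix, n_components: int = 2):
    """Eigendecomposition of a GRM for population-structure plots.

    Returns ``(scores, variance_fractions)``: scores are eigenvectors
    scaled by the square root of their (non-negative) eigenvalues;
    fractions are eigenvalues over the sum of eigenvalues floored at zero.
    """
    vals, vecs = np.linalg.eigh(G.values)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_neg = int((vals < 0).sum())
    if n_neg:
        logger.info("GRM has %d negative eigenvalue(s); floored at 0", n_neg)
    pos = np.maximum(vals, 0.0)
    total = pos.sum()
    rank = int((pos > 1e-12 * max(total, 1.0)).sum())
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but GRM rank is {rank}; truncating"
        )
        n_components = rank
    scores = vecs[:, :n_components] * np.sqrt(pos[:n_components])
    fractions = pos[:n_components] / total
    return scores, fractions


def ld_r2(G: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Composite LD: squared Pearson correlation of genotype dosages.

    Computed on pairwise-complete calls and clipped to [0,1]; returns NaN
    (with a warning) if either marker is monomorphic in the evaluated
    subset.  No phasing is attempted.
    """
    ids = G.markers["snp_id"]
    ia = ids[ids == snp_a].index
    ib = ids[ids == snp_b].index
    if len(ia) == 0 or len(ib) == 0:
        raise KeyError(f"marker not found: {snp_a if len(ia)==0 else snp_b}")
    x = G.calls[:, ia[0]].astype(float)
    y = G.calls[:, ib[0]].astype(float)
    ok = (x >= 0) & (y >= 0)
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        warnings.warn("LD undefined for monomorphic marker in subset")
        return float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r * r, 0.0, 1.0))
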
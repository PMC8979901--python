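"""Marker quality control and seeded allele-frequency imputation.

Filters mirror common SNP-array practice for livestock panels: duplicate
positions, call rate < 90%, minor allele frequency < 0.01 and a chi-square
Hardy-Weinberg test at p < 0.001, applied in that fixed order with each
marker attributed to the first rule it fails.  Non-autosomal markers are
excluded at read time already; the QC report keeps a slot for them so
counts reconcile.

Haplotype-based imputation is deliberately out of scope: missing calls are
drawn from Binomial(2, p-hat) at the observed allele frequency, which is
enough to complete the matrices for relationship building but carries no
linkage information — a documented fidelity gap relative to LD-aware
imputation of real array data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING_CALL, GenotypeMatrix

logger = logging.getLogger("ssgeval.qc")

REMOVAL_ORDER = ("nonautosomal", "duplicate", "callrate", "maf", "hwe")


@dataclass
class QCReport:
    """Per-rule removal counts plus a per-SNP removal-reason table."""

    n_input: int
    removed_nonautosomal: int = 0
    removed_duplicate: int = 0
    removed_callrate: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    n_output: int = 0
    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "reason"])
    )

    def __post_init__(self):
        removed = (
            self.removed_nonautosomal
            + self.removed_duplicate
            + self.removed_callrate
            + self.removed_maf
            + self.removed_hwe
        )
        if self.n_output != self.n_input - removed:
            raise ValueError(
                f"QC bookkeeping broken: {self.n_input} - {removed} != {self.n_output}"
            )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tcount\n")
            fh.write(f"n_input\t{self.n_input}\n")
            for rule in REMOVAL_ORDER:
                fh.write(f"removed_{rule}\t{getattr(self, 'removed_' + rule)}\n")
            fh.write(f"n_output\t{self.n_output}\n")
        self.table.to_csv(
            str(path) + ".reasons", sep="\t", index=False
        )


def hwe_test(nAA: int, nAB: int, nBB: int) -> float:
    """Chi-square (1 df) goodness-of-fit p-value for Hardy-Weinberg.

    Expected genotype counts are taken at the sample allele frequency.
    A monomorphic sample is in trivial equilibrium (p = 1).
    """
    if min(nAA, nAB, nBB) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = nAA + nAB + nBB
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * nAA + nAB) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    obs = np.array([nAA, nAB, nBB], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(calls: np.ndarray) -> np.ndarray:
    """Vectorised chi-square HWE p-values per marker column."""
    nBB = (calls == 2).sum(axis=0).astype(float)
    nAB = (calls == 1).sum(axis=0).astype(float)
    nAA = (calls == 0).sum(axis=0).astype(float)
    n = nAA + nAB + nBB
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * nBB + nAB) / (2 * n)
        eAA = n * (1 - p) ** 2
        eAB = 2 * n * p * (1 - p)
        eBB = n * p**2
        chi2 = (
            (nAA - eAA) ** 2 / eAA
            + (nAB - eAB) ** 2 / eAB
            + (nBB - eBB) ** 2 / eBB
        )
    out = stats.chi2.sf(chi2, df=1)
    mono = (p <= 0) | (p >= 1) | (n == 0)
    out[mono] = 1.0
    return out


def qc_filter(
    G: GenotypeMatrix,
    maf_min: float = 0.01,
    callrate_min: float = 0.90,
    hwe_p_min: float = 0.001,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply marker QC in a fixed order; marker order is preserved.

    Order of rules (each marker counted once, at its first failure):
    non-autosomal (excluded at read, counted as 0 here), duplicate
    ``(chrom, bp)`` (the lexicographically first ``snp_id`` is kept),
    call rate < ``callrate_min``, MAF < ``maf_min``, HWE p < ``hwe_p_min``.
    """
    m = G.n_markers
    reason = np.full(m, "", dtype="<U12")

    # duplicates: same (chrom, bp); keep first by snp_id order
    mk = G.markers
    dup_groups = mk.groupby(["chrom", "bp"], sort=False)
    for _, grp in dup_groups:
        if len(grp) > 1:
            keep = grp["snp_id"].sort_values().index[0]
            for i in grp.index:
                if i != keep:
                    reason[i] = "duplicate"

    calls = G.calls
    obs = calls >= 0
    n_animals = calls.shape[0]
    callrate = obs.sum(axis=0) / max(n_animals, 1)
    fresh = reason == ""
    reason[fresh & (callrate < callrate_min)] = "callrate"

    freq = G.allele_frequencies()
    maf = np.minimum(freq, 1 - freq)
    fresh = reason == ""
    with np.errstate(invalid="ignore"):
        fail_maf = np.where(np.isnan(maf), True, maf < maf_min)
    reason[fresh & fail_maf] = "maf"

    hwe_p = _hwe_pvalues(np.where(obs, calls, np.int8(-1)))
    fresh = reason == ""
    reason[fresh & (hwe_p < hwe_p_min)] = "hwe"

    keep = reason == ""
    report = QCReport(
        n_input=m,
        removed_duplicate=int((reason == "duplicate").sum()),
        removed_callrate=int((reason == "callrate").sum()),
        removed_maf=int((reason == "maf").sum()),
        removed_hwe=int((reason == "hwe").sum()),
        n_output=int(keep.sum()),
        table=pd.DataFrame(
            {
                "snp_id": mk.loc[~keep, "snp_id"].to_numpy(),
                "reason": reason[~keep],
            }
        ),
    )
    if report.n_output == 0:
        logger.warning("QC removed every marker")
    out = G.subset_markers(keep)
    return out, report


def impute_missing(G: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Fill missing calls by seeded sampling from Binomial(2, p-hat).

    ``p-hat`` is each marker's observed alleleB frequency.  A marker with
    no observed calls cannot be imputed and raises.  Matrices without
    missing calls are returned unchanged.
    """
    calls = G.calls
    miss = calls == MISSING_CALL
    if not miss.any():
        return G
    freq = G.allele_frequencies()
    dead = np.isnan(freq)
    if dead.any():
        bad = G.markers.loc[dead, "snp_id"].tolist()
        raise ValueError(f"cannot impute markers with all calls missing: {bad[:5]}")
    rng = np.random.default_rng(seed)
    draws = rng.binomial(2, np.broadcast_to(freq, calls.shape)).astype(np.int8)
    out = np.where(miss, draws, calls)
    logger.info("imputed %d missing call(s)", int(miss.sum()))
    return GenotypeMatrix(list(G.animal_ids), G.markers.copy(), out)
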
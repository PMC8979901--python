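"""Readers and writers for every external representation the pipeline touches.

Formats handled:

* pedigree CSV/TSV (animal, sire, dam, birth date, sex, breed),
* PLINK ``ped/map`` and binary ``bed/bim/fam`` (bed v1.00, SNP-major),
* phenotype TSV (withers height with measurement metadata),
* result tables (GWAS and breeding-value TSVs).

Genotype calls are coded as the count of *alleleB* — the second allele
column of the map/bim file — so the sign of SNP effects and the direction
of the genomic relationship matrix are stable across formats.

Unknown parents are written as ``"0"`` on disk (the PLINK convention) and
normalised to :data:`UNKNOWN_PARENT` internally.  Dates are ISO-8601 only.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ssgeval.io")

UNKNOWN_PARENT = "0"
#: sentinel for a missing genotype call in the int8 call matrix
MISSING_CALL = np.int8(-1)
#: autosome range accepted for the horse genome
MAX_AUTOSOME = 31

_UNKNOWN_TOKENS = {"", "0", "-", ".", "NA", "NaN", "nan", "none", "None"}

#: half-open age-class bins in years: [0,3) [3,4) [4,5) [5,6) [6,inf) -> 1..5
AGE_CLASS_EDGES = (3.0, 4.0, 5.0, 6.0)


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycles, duplicates, sex conflicts)."""


class FormatError(ValueError):
    """Malformed or mutually inconsistent input files."""


class ValidationError(ValueError):
    """Semantically invalid data (out-of-range values, unknown animals)."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


def _norm_parent(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return UNKNOWN_PARENT
    s = str(x).strip()
    return UNKNOWN_PARENT if s in _UNKNOWN_TOKENS else s


def _norm_sex(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "U"
    s = str(x).strip().upper()
    if s in {"F", "FEMALE", "2"}:
        return "F"
    if s in {"M", "MALE", "1"}:
        return "M"
    return "U"


class Pedigree:
    """A validated, topologically ordered pedigree.

    Parents always precede offspring in the stored order.  Unknown parents
    are index ``-1``.  Parents that are named but never defined are
    materialised as founder records (sires as male, dams as female).
    """

    def __init__(
        self,
        ids: Sequence[str],
        sire: np.ndarray,
        dam: np.ndarray,
        birth_date: Sequence[date | None],
        sex: Sequence[str],
        breed: Sequence[str],
        generation: np.ndarray | None = None,
    ):
        self.ids = list(ids)
        self.sire = np.asarray(sire, dtype=np.int64)
        self.dam = np.asarray(dam, dtype=np.int64)
        self.birth_date = list(birth_date)
        self.sex = np.asarray(sex, dtype="<U1")
        self.breed = list(breed)
        self.generation = (
            np.full(len(self.ids), -1, dtype=np.int64)
            if generation is None
            else np.asarray(generation, dtype=np.int64)
        )
        self._index = {a: i for i, a in enumerate(self.ids)}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        generations: dict[str, int] | None = None,
    ) -> "Pedigree":
        """Build from ``(animal, sire, dam, birth_date, sex, breed)`` tuples.

        Validates uniqueness, acyclicity and parent-sex consistency, adds
        implicit founders and reorders so parents precede offspring.
        """
        rows = [
            (
                str(a).strip(),
                _norm_parent(s),
                _norm_parent(d),
                bd if (bd is None or isinstance(bd, date)) else _parse_date(bd),
                _norm_sex(sx),
                "" if b is None else str(b).strip(),
            )
            for a, s, d, bd, sx, b in records
        ]
        ids = [r[0] for r in rows]
        seen: set[str] = set()
        dups = sorted({a for a in ids if a in seen or seen.add(a)})
        if dups:
            raise PedigreeError(f"duplicate animal ids: {dups}")
        known = set(ids)

        # implicit founders, sires first for a deterministic order
        implicit: dict[str, str] = {}
        for _, s, d, *_ in rows:
            if s != UNKNOWN_PARENT and s not in known and s not in implicit:
                implicit[s] = "M"
            if d != UNKNOWN_PARENT and d not in known and d not in implicit:
                implicit[d] = "F"
        for pid, sx in implicit.items():
            rows.append((pid, UNKNOWN_PARENT, UNKNOWN_PARENT, None, sx, ""))
        if implicit:
            logger.info("materialised %d implicit founder(s)", len(implicit))

        index = {r[0]: i for i, r in enumerate(rows)}
        n = len(rows)
        sire = np.array(
            [index[r[1]] if r[1] != UNKNOWN_PARENT else -1 for r in rows]
        )
        dam = np.array(
            [index[r[2]] if r[2] != UNKNOWN_PARENT else -1 for r in rows]
        )

        # parent-sex consistency
        for pcol, want, label in ((sire, "M", "sire"), (dam, "F", "dam")):
            bad = sorted(
                rows[p][0]
                for p in set(pcol[pcol >= 0].tolist())
                if rows[p][4] not in (want, "U")
            )
            if bad:
                raise PedigreeError(
                    f"animals used as {label} but recorded with the other sex: {bad}"
                )

        order = _topological_order(sire, dam, [r[0] for r in rows])
        rows = [rows[i] for i in order]
        remap = np.empty(n, dtype=np.int64)
        remap[order] = np.arange(n)
        new_index = {r[0]: i for i, r in enumerate(rows)}
        sire2 = np.array(
            [new_index[r[1]] if r[1] != UNKNOWN_PARENT else -1 for r in rows]
        )
        dam2 = np.array(
            [new_index[r[2]] if r[2] != UNKNOWN_PARENT else -1 for r in rows]
        )
        gen = None
        if generations is not None:
            gen = np.array([generations.get(r[0], -1) for r in rows])
        return cls(
            [r[0] for r in rows],
            sire2,
            dam2,
            [r[3] for r in rows],
            [r[4] for r in rows],
            [r[5] for r in rows],
            generation=gen,
        )

    # -- accessors ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Pedigree)
            and self.ids == other.ids
            and np.array_equal(self.sire, other.sire)
            and np.array_equal(self.dam, other.dam)
            and self.birth_date == other.birth_date
            and np.array_equal(self.sex, other.sex)
            and self.breed == other.breed
        )

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    def indices_of(self, animal_ids: Sequence[str]) -> np.ndarray:
        return np.array([self._index[a] for a in animal_ids], dtype=np.int64)

    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    def leaf_females(self) -> list[str]:
        """Females that are nobody's parent — the default phenotyped cohort.

        When generation tags are available (simulated pedigrees) the final
        generation's females are returned instead, which excludes childless
        females of earlier generations.
        """
        if (self.generation >= 0).any():
            g = self.generation.max()
            keep = (self.generation == g) & (self.sex == "F")
            return [a for a, k in zip(self.ids, keep) if k]
        is_parent = np.zeros(len(self), dtype=bool)
        is_parent[self.sire[self.sire >= 0]] = True
        is_parent[self.dam[self.dam >= 0]] = True
        return [
            a
            for a, par, sx in zip(self.ids, is_parent, self.sex)
            if not par and sx == "F"
        ]


def _topological_order(
    sire: np.ndarray, dam: np.ndarray, ids: Sequence[str]
) -> list[int]:
    """Stable Kahn ordering (parents first); raises naming a cycle member."""
    import heapq

    n = len(ids)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p >= 0:
                children[p].append(i)
                indeg[i] += 1
    heap = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(heap)
    out: list[int] = []
    while heap:
        i = heapq.heappop(heap)
        out.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, c)
    if len(out) < n:
        member = ids[int(np.nonzero(indeg > 0)[0][0])]
        raise PedigreeError(
            f"pedigree contains a cycle; '{member}' is its own ancestor"
        )
    return out


def _parse_date(x) -> date | None:
    if x is None:
        return None
    if isinstance(x, datetime):
        return x.date()
    if isinstance(x, date):
        return x
    s = str(x).strip()
    if s in _UNKNOWN_TOKENS:
        return None
    try:
        return datetime.strptime(s, "%Y-%m-%d").date()
    except ValueError as e:
        raise ValidationError(f"date '{s}' is not ISO-8601 (YYYY-MM-DD)") from e


_PED_COLUMNS = ["animal_id", "sire_id", "dam_id", "birth_date", "sex", "breed"]


def read_pedigree(path, dialect: str | None = None) -> Pedigree:
    """Read a pedigree table; ``dialect`` is ``csv``/``tsv`` (default: by suffix)."""
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".txt"} else "csv"
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _PED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pedigree file lacks columns {missing}")
    return Pedigree.from_records(
        (r.animal_id, r.sire_id, r.dam_id, r.birth_date or None, r.sex, r.breed)
        for r in df.itertuples()
    )


def write_pedigree(ped: Pedigree, path, dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".txt"} else "csv"
    sep = "\t" if dialect == "tsv" else ","
    df = pd.DataFrame(
        {
            "animal_id": ped.ids,
            "sire_id": [
                ped.ids[s] if s >= 0 else UNKNOWN_PARENT for s in ped.sire
            ],
            "dam_id": [ped.ids[d] if d >= 0 else UNKNOWN_PARENT for d in ped.dam],
            "birth_date": [
                "" if b is None else b.isoformat() for b in ped.birth_date
            ],
            "sex": ped.sex,
            "breed": ped.breed,
        }
    )
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


class GenotypeMatrix:
    """Animals x SNPs call matrix with its marker map.

    ``calls[i, j]`` counts copies of ``alleleB`` for animal ``i`` at marker
    ``j`` (``-1`` = missing).  Markers are kept sorted by ``(chrom, bp)``
    and restricted to autosomes 1..31.
    """

    def __init__(self, animal_ids: Sequence[str], markers: pd.DataFrame, calls):
        calls = np.asarray(calls, dtype=np.int8)
        markers = markers.reset_index(drop=True)
        required = ["snp_id", "chrom", "bp", "alleleA", "alleleB"]
        if list(markers.columns[:5]) != required:
            markers = markers[required]
        if calls.shape != (len(animal_ids), len(markers)):
            raise ValidationError(
                f"call matrix {calls.shape} does not match "
                f"{len(animal_ids)} animals x {len(markers)} markers"
            )
        bad = ~np.isin(calls, (-1, 0, 1, 2))
        if bad.any():
            raise ValidationError("genotype calls outside {0,1,2,missing}")
        chrom = markers["chrom"].to_numpy()
        if ((chrom < 1) | (chrom > MAX_AUTOSOME)).any():
            raise ValidationError(f"chromosome codes outside 1..{MAX_AUTOSOME}")
        order = np.lexsort((markers["bp"].to_numpy(), chrom))
        if not np.array_equal(order, np.arange(len(markers))):
            markers = markers.iloc[order].reset_index(drop=True)
            calls = calls[:, order]
        self.animal_ids = list(animal_ids)
        self.markers = markers
        self.calls = calls
        self._index = {a: i for i, a in enumerate(self.animal_ids)}

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.animal_ids == other.animal_ids
            and self.markers.equals(other.markers)
            and np.array_equal(self.calls, other.calls)
        )

    def subset_animals(self, animal_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._index[a] for a in animal_ids]
        return GenotypeMatrix(
            list(animal_ids), self.markers.copy(), self.calls[idx]
        )

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            keep = np.nonzero(mask)[0]
        else:
            keep = mask
        return GenotypeMatrix(
            list(self.animal_ids),
            self.markers.iloc[keep].reset_index(drop=True),
            self.calls[:, keep],
        )

    def allele_frequencies(self) -> np.ndarray:
        """Observed alleleB frequency per marker, ignoring missing calls."""
        c = self.calls.astype(np.float64)
        obs = c >= 0
        with np.errstate(invalid="ignore"):
            return np.where(
                obs.sum(axis=0) > 0,
                np.where(obs, c, 0.0).sum(axis=0) / (2.0 * obs.sum(axis=0)),
                np.nan,
            )


def _read_marker_map(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        dtype=str,
        comment=None,
    )
    if df.shape[1] == 4:  # .map: chrom snp cM bp
        df.columns = ["chrom", "snp_id", "cm", "bp"]
        df["alleleA"], df["alleleB"] = "A", "B"
    elif df.shape[1] == 6:  # .bim: chrom snp cM bp a1 a2
        df.columns = ["chrom", "snp_id", "cm", "bp", "alleleA", "alleleB"]
    else:
        raise FormatError(f"marker map {path} has {df.shape[1]} columns")
    df["bp"] = df["bp"].astype(np.int64)
    return df


def _drop_non_autosomal(markers: pd.DataFrame, where: str) -> pd.DataFrame:
    num = pd.to_numeric(markers["chrom"], errors="coerce")
    keep = num.notna() & (num >= 1) & (num <= MAX_AUTOSOME)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: dropped %d non-autosomal marker(s)", where, dropped)
    out = markers.loc[keep].copy()
    out["chrom"] = num[keep].astype(np.int64)
    return out


def read_genotypes(prefix, format: str = "ped/map") -> GenotypeMatrix:
    """Read PLINK text (``ped/map``) or binary (``bed/bim/fam``) genotypes."""
    prefix = Path(prefix)
    if format == "ped/map":
        return _read_ped_map(prefix)
    if format == "bed/bim/fam":
        return _read_bed(prefix)
    raise ValueError(f"unknown genotype format '{format}'")


def write_genotypes(
    g: GenotypeMatrix, prefix, format: str = "ped/map"
) -> None:
    prefix = Path(prefix)
    if format == "ped/map":
        _write_ped_map(g, prefix)
    elif format == "bed/bim/fam":
        _write_bed(g, prefix)
    else:
        raise ValueError(f"unknown genotype format '{format}'")


def _read_ped_map(prefix: Path) -> GenotypeMatrix:
    """Read PLINK text genotypes.

    A ``.map`` file carries no allele columns, so the allele coding is
    inferred per marker from the observed alleles: the alphabetically
    first becomes alleleA, the second alleleB (the counted allele).  A
    marker where only one allele is ever seen gets alleleB = "0" and all
    dosages 0; more than two observed alleles is a format error.
    """
    markers = _read_marker_map(prefix.with_suffix(".map"))
    num = pd.to_numeric(markers["chrom"], errors="coerce")
    keep_mask = (num.notna() & (num >= 1) & (num <= MAX_AUTOSOME)).to_numpy()
    m_total = len(markers)
    markers = _drop_non_autosomal(markers, str(prefix))
    m = len(markers)
    ids: list[str] = []
    pairs: list[np.ndarray] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m_total:
                raise FormatError(
                    f"{prefix}.ped line {ln}: {len(parts)} fields, expected "
                    f"{6 + 2 * m_total} for {m_total} markers"
                )
            ids.append(parts[1])
            pairs.append(
                np.array(parts[6:], dtype="<U8").reshape(m_total, 2)[keep_mask]
            )
    al = (
        np.stack(pairs)  # animals x markers x 2
        if pairs
        else np.empty((0, m, 2), dtype="<U8")
    )
    allele_a = np.full(m, "0", dtype="<U8")
    allele_b = np.full(m, "0", dtype="<U8")
    for j in range(m):
        seen = sorted(set(al[:, j, :].ravel()) - {"0"})
        if len(seen) > 2:
            raise FormatError(
                f"{prefix}.ped: marker {markers['snp_id'].iloc[j]} has "
                f"{len(seen)} distinct alleles"
            )
        if len(seen) >= 1:
            allele_a[j] = seen[0]
        if len(seen) == 2:
            allele_b[j] = seen[1]
    known = (al != "0").all(axis=2)
    if ((al == "0").sum(axis=2) == 1).any():
        raise FormatError(f"{prefix}.ped: half-missing genotype call")
    calls = np.where(
        known,
        (al[:, :, 0] == allele_b).astype(np.int8)
        + (al[:, :, 1] == allele_b).astype(np.int8),
        MISSING_CALL,
    ).astype(np.int8)
    markers = markers.assign(alleleA=allele_a, alleleB=allele_b)
    markers = markers[["snp_id", "chrom", "bp", "alleleA", "alleleB"]]
    return GenotypeMatrix(ids, markers.reset_index(drop=True), calls)


def _write_ped_map(g: GenotypeMatrix, prefix: Path) -> None:
    with open(prefix.with_suffix(".map"), "w") as fh:
        for r in g.markers.itertuples():
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.bp}\n")
    a = g.markers["alleleA"].to_numpy()
    b = g.markers["alleleB"].to_numpy()
    lut = np.empty((4, g.n_markers, 2), dtype="<U8")
    lut[0] = np.stack([a, a], axis=1)
    lut[1] = np.stack([a, b], axis=1)
    lut[2] = np.stack([b, b], axis=1)
    lut[3] = "0"
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, aid in enumerate(g.animal_ids):
            c = g.calls[i].astype(np.int64)
            c = np.where(c < 0, 3, c)
            pairs = lut[c, np.arange(g.n_markers)]
            fh.write(
                f"FAM0 {aid} 0 0 0 -9 " + " ".join(pairs.ravel()) + "\n"
            )


_BED_MAGIC = b"\x6c\x1b\x01"
# bed 2-bit codes (SNP-major): 00 hom alleleA, 01 missing, 10 het, 11 hom alleleB
_BED_FROM_CALL = {0: 0b00, -1: 0b01, 1: 0b10, 2: 0b11}
_CALL_FROM_BED = np.array([0, -1, 1, 2], dtype=np.int8)


def _read_bed(prefix: Path) -> GenotypeMatrix:
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str)
    ids = fam[1].tolist()
    markers = _read_marker_map(prefix.with_suffix(".bim"))
    m_total = len(markers)
    n = len(ids)
    data = Path(prefix.with_suffix(".bed")).read_bytes()
    if data[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (want v1.00 SNP-major)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m_total
    if len(data) != expected:
        raise FormatError(
            f"{prefix}.bed: {len(data)} bytes, expected {expected} for "
            f"{n} samples x {m_total} SNPs"
        )
    raw = np.frombuffer(data, dtype=np.uint8, offset=3).reshape(
        m_total, bytes_per_snp
    )
    # unpack 2-bit fields, sample-fastest within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (raw[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m_total, -1)[:, :n]
    calls = _CALL_FROM_BED[codes].T  # animals x markers
    num = pd.to_numeric(markers["chrom"], errors="coerce")
    keep = (num.notna() & (num >= 1) & (num <= MAX_AUTOSOME)).to_numpy()
    if not keep.all():
        logger.info("%s: dropped %d non-autosomal marker(s)", prefix, int((~keep).sum()))
    markers = markers.loc[keep].copy()
    markers["chrom"] = num[keep].astype(np.int64)
    calls = calls[:, keep]
    markers = markers[["snp_id", "chrom", "bp", "alleleA", "alleleB"]]
    return GenotypeMatrix(ids, markers.reset_index(drop=True), np.ascontiguousarray(calls))


def _write_bed(g: GenotypeMatrix, prefix: Path) -> None:
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for r in g.markers.itertuples():
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.bp}\t{r.alleleA}\t{r.alleleB}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for aid in g.animal_ids:
            fh.write(f"FAM0 {aid} 0 0 0 -9\n")
    n, m = g.n_animals, g.n_markers
    code_lut = np.array([0b00, 0b10, 0b11], dtype=np.uint8)
    codes = np.where(
        g.calls.T < 0, np.uint8(0b01), code_lut[np.clip(g.calls.T, 0, 2)]
    ).astype(np.uint8)
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((m, pad), dtype=np.uint8)], axis=1
        )
    codes = codes.reshape(m, -1, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def age_class(age_years: float) -> int:
    """Map age at measurement to classes 1..5 via half-open bins.

    ``[0,3) -> 1, [3,4) -> 2, [4,5) -> 3, [5,6) -> 4, [6,inf) -> 5``.
    """
    return 1 + int(np.digitize(age_years, AGE_CLASS_EDGES, right=False))


@dataclass
class PhenotypeTable:
    """Withers-height records joined with measurement age and age class."""

    data: pd.DataFrame
    height_range: tuple[float, float] = (100.0, 200.0)

    COLUMNS = (
        "animal_id",
        "height",
        "measurement_date",
        "source",
        "age",
        "age_class",
    )

    def __post_init__(self):
        df = self.data
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"phenotype table lacks columns {missing}")
        lo, hi = self.height_range
        bad = df.loc[(df["height"] < lo) | (df["height"] > hi), "animal_id"]
        if len(bad):
            raise ValidationError(
                f"withers height outside plausible range [{lo},{hi}] cm for "
                f"{bad.tolist()[:10]}"
            )
        expect = df["age"].map(age_class)
        if not (expect.to_numpy() == df["age_class"].to_numpy()).all():
            raise ValidationError("age_class inconsistent with age under the binning rule")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def animal_ids(self) -> list[str]:
        return self.data["animal_id"].tolist()


def read_phenotypes(
    path, pedigree: Pedigree, height_range=(100.0, 200.0)
) -> PhenotypeTable:
    """Read a phenotype TSV and derive measurement ages from the pedigree.

    Age is ``(measurement_date - birth_date)`` in fractional years
    (365.25-day years); the age class follows the half-open bins of
    :func:`age_class`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["animal_id", "withers_height", "measurement_date", "source"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"phenotype file lacks columns {missing}")
    unknown = sorted(set(df["animal_id"]) - set(pedigree.ids))
    if unknown:
        raise ValidationError(f"phenotypes for animals not in pedigree: {unknown}")
    bad_src = sorted(set(df["source"]) - {"SBR", "MPT"})
    if bad_src:
        raise ValidationError(f"unknown phenotype source codes: {bad_src}")
    ages = []
    for r in df.itertuples():
        bd = pedigree.birth_date[pedigree.index_of(r.animal_id)]
        if bd is None:
            raise ValidationError(f"animal {r.animal_id} has no birth date")
        md = _parse_date(r.measurement_date)
        age = (md - bd).days / 365.25
        if age < 0:
            raise ValidationError(
                f"animal {r.animal_id} measured before birth (age {age:.2f} y)"
            )
        ages.append(age)
    out = pd.DataFrame(
        {
            "animal_id": df["animal_id"],
            "height": df["withers_height"].astype(float),
            "measurement_date": [
                _parse_date(x) for x in df["measurement_date"]
            ],
            "source": df["source"],
            "age": ages,
            "age_class": [age_class(a) for a in ages],
        }
    )
    return PhenotypeTable(out, height_range=height_range)


def write_phenotypes(table: PhenotypeTable, path) -> None:
    df = table.data
    pd.DataFrame(
        {
            "animal_id": df["animal_id"],
            "withers_height": [_fmt(x) for x in df["height"]],
            "measurement_date": [d.isoformat() for d in df["measurement_date"]],
            "source": df["source"],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return f"{x:.6g}"


_GWAS_COLUMNS = ["chrom", "snp_id", "bp", "alleleB", "freq", "beta", "se", "p"]
_EBV_COLUMNS = ["animal_id", "gebv", "pev", "reliability"]


def write_results(result, path) -> None:
    """Write a GWAS or breeding-value table as TSV (floats at 6 sig. digits).

    Dispatches on the object: anything with a ``.table`` DataFrame holding
    GWAS columns is written as a GWAS table; anything with per-animal
    ``gebv``/``pev`` (a model fit) as an EBV table.
    """
    if hasattr(result, "table"):
        df = result.table
        out = pd.DataFrame(
            {
                c: (
                    df[c].map(_fmt)
                    if df[c].dtype.kind == "f"
                    else df[c]
                )
                for c in _GWAS_COLUMNS
            }
        )
    elif hasattr(result, "gebv"):
        rel = result.reliability
        out = pd.DataFrame(
            {
                "animal_id": result.animal_ids,
                "gebv": [_fmt(x) for x in result.gebv],
                "pev": [_fmt(x) for x in result.pev],
                "reliability": [_fmt(x) for x in rel],
            }
        )
    else:
        raise TypeError(f"cannot serialise result of type {type(result)!r}")
    out.to_csv(path, sep="\t", index=False)


def read_ebv_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df[_EBV_COLUMNS]


def read_gwas_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df[_GWAS_COLUMNS]
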
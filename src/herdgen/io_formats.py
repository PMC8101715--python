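"""Canonical in-memory data model and readers/writers for PLINK and pedigree files.

Genotypes are held as counts of a designated *counted allele* (0/1/2, with -1
for a missing call), alongside a sorted autosomal SNP map.  Coordinates are
1-based inclusive base pairs (PLINK convention); segment and coverage lengths
in kb are ``(end - start + 1) / 1000``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "SnpMap",
    "GenotypeDataset",
    "Pedigree",
    "PedigreeRecord",
    "FormatError",
    "read_plink_text",
    "write_plink_text",
    "read_plink_bed",
    "write_plink_bed",
    "read_pedigree",
    "write_pedigree",
]


class FormatError(ValueError):
    """Raised for malformed genotype or pedigree files."""


# ---------------------------------------------------------------------------
# SNP map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpMap:
    """Sorted autosomal SNP map.

    Parameters
    ----------
    snp_ids, chromosomes, positions_bp
        Parallel arrays, sorted by (chromosome, position).  Chromosomes are
        integers (autosomes, 1..26 for sheep).  Positions are 1-based bp.
    allele1, allele2
        Allele symbols per SNP; ``allele1`` is the counted allele.
    """

    snp_ids: np.ndarray
    chromosomes: np.ndarray
    positions_bp: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.snp_ids)
        for name in ("chromosomes", "positions_bp", "allele1", "allele2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"SnpMap field {name} has wrong length")
        order = np.lexsort((self.positions_bp, self.chromosomes))
        if not np.array_equal(order, np.arange(n)):
            raise ValueError("SnpMap must be sorted by (chromosome, position)")
        for c in np.unique(self.chromosomes):
            pos = self.positions_bp[self.chromosomes == c]
            if np.any(np.diff(pos) == 0):
                raise FormatError(f"duplicate bp position on chromosome {c}")

    @classmethod
    def from_arrays(cls, snp_ids, chromosomes, positions_bp, allele1=None, allele2=None) -> "SnpMap":
        """Build a map from unsorted arrays, sorting canonically."""
        snp_ids = np.asarray(snp_ids, dtype=object)
        chromosomes = np.asarray(chromosomes, dtype=np.int64)
        positions_bp = np.asarray(positions_bp, dtype=np.int64)
        n = len(snp_ids)
        if allele1 is None:
            allele1 = np.full(n, "A", dtype=object)
        if allele2 is None:
            allele2 = np.full(n, "B", dtype=object)
        allele1 = np.asarray(allele1, dtype=object)
        allele2 = np.asarray(allele2, dtype=object)
        order = np.lexsort((positions_bp, chromosomes))
        return cls(
            snp_ids[order],
            chromosomes[order],
            positions_bp[order],
            allele1[order],
            allele2[order],
        )

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def chromosome_list(self) -> np.ndarray:
        return np.unique(self.chromosomes)

    def chromosome_slice(self, chrom: int) -> slice:
        idx = np.flatnonzero(self.chromosomes == chrom)
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def coverage_kb(self, chrom: int) -> float:
        """Chromosome coverage length in kb: span of its SNPs, inclusive."""
        sl = self.chromosome_slice(chrom)
        pos = self.positions_bp[sl]
        if pos.size == 0:
            return 0.0
        return (int(pos[-1]) - int(pos[0]) + 1) / 1000.0

    @property
    def l_auto_kb(self) -> float:
        """Total autosomal coverage (kb): sum of per-chromosome spans."""
        return float(sum(self.coverage_kb(int(c)) for c in self.chromosome_list()))

    def subset(self, mask: np.ndarray) -> "SnpMap":
        mask = np.asarray(mask)
        return SnpMap(
            self.snp_ids[mask],
            self.chromosomes[mask],
            self.positions_bp[mask],
            self.allele1[mask],
            self.allele2[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chromosome": self.chromosomes,
                "position_bp": self.positions_bp,
                "allele1": self.allele1,
                "allele2": self.allele2,
            }
        )


# ---------------------------------------------------------------------------
# Genotype dataset
# ---------------------------------------------------------------------------


@dataclass
class GenotypeDataset:
    """Individuals x SNPs genotype matrix plus its SNP map.

    ``calls[i, j]`` is the number of copies of the counted allele (0, 1, 2)
    or :data:`MISSING`.
    """

    snp_map: SnpMap
    individual_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individual_ids), self.snp_map.n_snps):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {self.snp_map.n_snps} SNPs"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise FormatError("duplicate individual IDs")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls must be in {0,1,2,missing}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return self.snp_map.n_snps

    def missing_rate_per_snp(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def missing_rate_per_individual(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def subset(self, individuals=None, snps=None) -> "GenotypeDataset":
        """Subset by individual and/or SNP index or boolean mask."""
        calls = self.calls
        ids = self.individual_ids
        smap = self.snp_map
        if individuals is not None:
            individuals = np.asarray(individuals)
            if individuals.dtype == bool:
                individuals = np.flatnonzero(individuals)
            calls = calls[individuals]
            ids = [self.individual_ids[i] for i in individuals]
        if snps is not None:
            snps = np.asarray(snps)
            calls = calls[:, snps]
            smap = smap.subset(snps)
        return GenotypeDataset(smap, list(ids), calls.copy())


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

UNKNOWN = None


@dataclass(frozen=True)
class PedigreeRecord:
    individual_id: str
    sire_id: str | None
    dam_id: str | None
    sex: str = "unknown"  # {male, female, unknown}
    birth_year: int | None = None


class Pedigree:
    """Validated directed-acyclic pedigree.

    Individuals referenced only as parents are materialised as founder
    records.  Validation rejects cycles and IDs used both as sire and dam.
    """

    def __init__(self, records: list[PedigreeRecord]):
        recs: dict[str, PedigreeRecord] = {}
        for r in records:
            if r.individual_id in recs:
                raise FormatError(f"duplicate individual ID {r.individual_id!r}")
            recs[r.individual_id] = r
        # materialise parents that have no record of their own
        sires = {r.sire_id for r in records if r.sire_id is not None}
        dams = {r.dam_id for r in records if r.dam_id is not None}
        clash = sires & dams
        if clash:
            raise FormatError(f"IDs used both as sire and as dam: {sorted(clash)}")
        for pid in sorted(sires - recs.keys()):
            recs[pid] = PedigreeRecord(pid, None, None, "male", None)
        for pid in sorted(dams - recs.keys()):
            recs[pid] = PedigreeRecord(pid, None, None, "female", None)
        for pid, r in list(recs.items()):
            # a recorded sire must not be female, and vice versa
            if pid in sires and recs[pid].sex == "female":
                raise FormatError(f"{pid!r} recorded female but used as sire")
            if pid in dams and recs[pid].sex == "male":
                raise FormatError(f"{pid!r} recorded male but used as dam")
        self._records = recs
        self._order = self._toposort()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_tuples(cls, rows) -> "Pedigree":
        """rows: iterable of (id, sire|None, dam|None[, sex[, birth_year]])."""
        recs = []
        for row in rows:
            row = tuple(row)
            iid, sire, dam = row[:3]
            sex = row[3] if len(row) > 3 else "unknown"
            by = row[4] if len(row) > 4 else None
            recs.append(PedigreeRecord(str(iid), sire, dam, sex, by))
        return cls(recs)

    def _toposort(self) -> list[str]:
        """Kahn topological order, parents before offspring; cycle -> error."""
        children: dict[str, list[str]] = {i: [] for i in self._records}
        indeg = {i: 0 for i in self._records}
        for r in self._records.values():
            for p in (r.sire_id, r.dam_id):
                if p is not None:
                    if p == r.individual_id:
                        raise FormatError(f"{p!r} is its own parent")
                    children[p].append(r.individual_id)
                    indeg[r.individual_id] += 1
        queue = sorted(i for i, d in indeg.items() if d == 0)
        order: list[str] = []
        import heapq

        heapq.heapify(queue)
        while queue:
            i = heapq.heappop(queue)
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    heapq.heappush(queue, c)
        if len(order) != len(self._records):
            cyc = sorted(i for i, d in indeg.items() if d > 0)
            raise FormatError(f"pedigree contains a cycle involving {cyc}")
        return order

    # -- accessors ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, iid: str) -> bool:
        return iid in self._records

    def __iter__(self):
        return iter(self._order)

    @property
    def ids(self) -> list[str]:
        """IDs in topological order (parents before offspring)."""
        return list(self._order)

    def record(self, iid: str) -> PedigreeRecord:
        return self._records[iid]

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        r = self._records[iid]
        return r.sire_id, r.dam_id

    def is_founder(self, iid: str) -> bool:
        s, d = self.parents(iid)
        return s is None and d is None

    def founders(self) -> list[str]:
        return [i for i in self._order if self.is_founder(i)]

    def offspring_counts(self) -> dict[str, int]:
        counts = {i: 0 for i in self._records}
        for r in self._records.values():
            for p in (r.sire_id, r.dam_id):
                if p is not None:
                    counts[p] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "individual_id": r.individual_id,
                "sire_id": r.sire_id,
                "dam_id": r.dam_id,
                "sex": r.sex,
                "birth_year": r.birth_year,
            }
            for r in (self._records[i] for i in self._order)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------------


def _read_map(map_path) -> tuple[list[str], list[int], list[int]]:
    snp_ids, chroms, poss = [], [], []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{map_path}: line {ln}: expected 4 columns, got {len(parts)}")
            chrom, snp_id, _cm, bp = parts
            chroms.append(int(chrom))
            snp_ids.append(snp_id)
            poss.append(int(bp))
    return snp_ids, chroms, poss


def read_plink_text(ped_path, map_path, counted: str = "minor") -> GenotypeDataset:
    """Read a PLINK text fileset (PED + MAP).

    ``"0 0"`` genotypes become missing.  ``counted`` selects the counted
    allele: ``"minor"`` (default, within-file minor allele) or ``"major"``.
    """
    snp_ids, chroms, poss = _read_map(map_path)
    n_snp = len(snp_ids)
    ids: list[str] = []
    rows: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_snp:
                raise FormatError(
                    f"{ped_path}: row {ln}: expected {6 + 2 * n_snp} fields "
                    f"(6 + 2x{n_snp} SNPs), got {len(parts)}"
                )
            iid = parts[1]
            if iid in ids:
                raise FormatError(f"{ped_path}: row {ln}: duplicate individual ID {iid!r}")
            ids.append(iid)
            rows.append(parts[6:])
    n_ind = len(ids)
    a_mat = np.empty((n_ind, n_snp), dtype=object)
    b_mat = np.empty((n_ind, n_snp), dtype=object)
    for i, alleles in enumerate(rows):
        a_mat[i] = alleles[0::2]
        b_mat[i] = alleles[1::2]

    calls = np.full((n_ind, n_snp), MISSING, dtype=np.int8)
    allele1 = np.empty(n_snp, dtype=object)
    allele2 = np.empty(n_snp, dtype=object)
    for j in range(n_snp):
        a = a_mat[:, j]
        b = b_mat[:, j]
        missing = (a == "0") | (b == "0")
        if np.any((a == "0") != (b == "0")):
            raise FormatError(f"{ped_path}: SNP {snp_ids[j]}: half-missing genotype")
        obs = np.concatenate([a[~missing], b[~missing]])
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) > 2:
            raise FormatError(f"{ped_path}: SNP {snp_ids[j]}: more than 2 alleles {list(uniq)}")
        if len(uniq) == 0:
            allele1[j], allele2[j] = "A", "B"
            continue
        if len(uniq) == 1:
            uniq = np.append(uniq, "0")  # monomorphic: placeholder other allele
            counts = np.append(counts, 0)
        # counted allele: minor (ties broken by symbol order, PLINK-like)
        order = np.lexsort((uniq, counts))
        minor, major = uniq[order[0]], uniq[order[1]]
        cnt = minor if counted == "minor" else major
        other = major if counted == "minor" else minor
        allele1[j], allele2[j] = cnt, other
        dos = (a == cnt).astype(np.int8) + (b == cnt).astype(np.int8)
        calls[:, j] = np.where(missing, MISSING, dos)

    smap = SnpMap.from_arrays(snp_ids, chroms, poss, allele1, allele2)
    # re-order calls to the map's canonical sort
    order = np.lexsort((np.asarray(poss), np.asarray(chroms)))
    return GenotypeDataset(smap, ids, calls[:, order])


def write_plink_text(dataset: GenotypeDataset, ped_path, map_path) -> None:
    """Write a PED/MAP fileset readable by PLINK."""
    m = dataset.snp_map
    with open(map_path, "w") as fh:
        for j in range(m.n_snps):
            fh.write(f"{m.chromosomes[j]} {m.snp_ids[j]} 0 {m.positions_bp[j]}\n")
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(dataset.individual_ids):
            fields = [iid, iid, "0", "0", "0", "-9"]
            row = dataset.calls[i]
            for j in range(m.n_snps):
                g = row[j]
                a1, a2 = m.allele1[j], m.allele2[j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [a2, a2]
                elif g == 1:
                    fields += [a1, a2]
                else:
                    fields += [a1, a1]
            fh.write(" ".join(map(str, fields)) + "\n")


# ---------------------------------------------------------------------------
# PLINK binary (BED/BIM/FAM), v1.0 SNP-major
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b"
# 2-bit codes, SNP-major: 00=hom allele1(A1A1), 01=missing, 10=het, 11=hom A2
_CODE_TO_CALL = np.array([2, MISSING, 1, 0], dtype=np.int8)
_CALL_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink_bed(bed_path, bim_path, fam_path) -> GenotypeDataset:
    """Read a PLINK 1 binary fileset (BED/BIM/FAM, SNP-major).

    A1 in the BIM is taken as the counted allele (PLINK convention).
    """
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cm", "position_bp", "a1", "a2"],
        dtype={"snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    ids = fam[1].tolist()
    n_ind, n_snp = len(ids), len(bim)
    raw = Path(bed_path).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes {raw[:2]!r}")
    if raw[2:3] != b"\x01":
        raise FormatError(f"{bed_path}: not SNP-major (mode byte {raw[2]:#x})")
    bytes_per_snp = (n_ind + 3) // 4
    expected = 3 + bytes_per_snp * n_snp
    if len(raw) != expected:
        raise FormatError(
            f"{bed_path}: truncated/oversized at byte {len(raw)} (expected {expected})"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(n_snp, bytes_per_snp)
    # unpack 2-bit codes, little-endian within byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(n_snp, bytes_per_snp * 4)[:, :n_ind]
    calls = _CODE_TO_CALL[codes].T  # -> individuals x SNPs

    smap = SnpMap.from_arrays(
        bim["snp_id"].to_numpy(object),
        bim["chromosome"].to_numpy(np.int64),
        bim["position_bp"].to_numpy(np.int64),
        bim["a1"].to_numpy(object),
        bim["a2"].to_numpy(object),
    )
    order = np.lexsort((bim["position_bp"].to_numpy(), bim["chromosome"].to_numpy()))
    return GenotypeDataset(smap, ids, np.ascontiguousarray(calls[:, order]))


def write_plink_bed(dataset: GenotypeDataset, bed_path, bim_path, fam_path) -> None:
    """Write a PLINK 1 binary fileset (SNP-major) readable by PLINK."""
    m = dataset.snp_map
    with open(bim_path, "w") as fh:
        for j in range(m.n_snps):
            fh.write(
                f"{m.chromosomes[j]}\t{m.snp_ids[j]}\t0\t{m.positions_bp[j]}"
                f"\t{m.allele1[j]}\t{m.allele2[j]}\n"
            )
    with open(fam_path, "w") as fh:
        for iid in dataset.individual_ids:
            fh.write(f"{iid} {iid} 0 0 0 -9\n")
    n_ind = dataset.n_individuals
    bytes_per_snp = (n_ind + 3) // 4
    code_lut = np.zeros(4, dtype=np.uint8)
    for call, code in _CALL_TO_CODE.items():
        code_lut[call if call != MISSING else 3] = code
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        buf = np.zeros((m.n_snps, bytes_per_snp * 4), dtype=np.uint8)
        calls = dataset.calls.T  # SNP-major
        idx = np.where(calls == MISSING, 3, calls)
        buf[:, :n_ind] = code_lut[idx]
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        packed = (buf.reshape(m.n_snps, bytes_per_snp, 4) << shifts).sum(axis=2).astype(np.uint8)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Pedigree files
# ---------------------------------------------------------------------------


def read_pedigree(
    path,
    sep: str = ",",
    unknown_token: str = "0",
    columns: dict | None = None,
) -> Pedigree:
    """Read a delimited pedigree file with a header.

    Expected columns (remappable via ``columns``): ``individual_id``,
    ``sire_id``, ``dam_id``, and optionally ``sex`` (m/f/male/female) and
    ``birth_year``.  ``unknown_token`` (default "0") marks unknown parents.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if columns:
        df = df.rename(columns=columns)
    needed = {"individual_id", "sire_id", "dam_id"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(needed - set(df.columns))}")

    def _parent(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
            return None
        v = str(v).strip()
        return None if v == unknown_token or v == "" else v

    sex_map = {"m": "male", "male": "male", "1": "male", "f": "female", "female": "female", "2": "female"}
    recs = []
    for _, row in df.iterrows():
        sex = "unknown"
        if "sex" in df.columns and not pd.isna(row.get("sex")):
            sex = sex_map.get(str(row["sex"]).strip().lower(), "unknown")
        by = None
        if "birth_year" in df.columns and not pd.isna(row.get("birth_year")):
            by = int(float(row["birth_year"]))
        recs.append(
            PedigreeRecord(
                str(row["individual_id"]).strip(),
                _parent(row["sire_id"]),
                _parent(row["dam_id"]),
                sex,
                by,
            )
        )
    return Pedigree(recs)


def write_pedigree(pedigree: Pedigree, path, sep: str = ",", unknown_token: str = "0") -> None:
    df = pedigree.to_frame()
    df["sire_id"] = df["sire_id"].fillna(unknown_token)
    df["dam_id"] = df["dam_id"].fillna(unknown_token)
    df.to_csv(path, sep=sep, index=False)
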
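"""Alignment and haplotype-table input/output.

Sequence data enter the pipeline as an aligned FASTA of equal-length mtDNA
sequences plus a population map assigning every sequence to a collecting
locality and every locality to a haplogroup (a clade-level lineage label such
as the four mountain-system lineages MSM/QLM/MCM/TPM of the Chinese white
pine beetle *Dendroctonus armandi*).  Count-only data enter as a
haplotype-frequency table: one row per locality with ``H##(count)`` tokens.

Haplogroup labels are consumed as input (typically derived from a
phylogenetic analysis done elsewhere); this module never infers them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = set("ACGTN-")

#: site policies for handling alignment columns containing gaps or Ns
COMPLETE_DELETION = "complete"  # drop columns containing '-' or 'N'
STRICT = "strict"               # compare full strings as-is

__all__ = [
    "Alignment",
    "PopulationMap",
    "HaplotypeTable",
    "AlignmentError",
    "InputError",
    "read_alignment",
    "write_alignment",
    "collapse_haplotypes",
    "parse_haplotype_table",
    "write_haplotype_table",
    "subset_by_group",
    "load_example_table",
]


class AlignmentError(ValueError):
    """Raised for structurally invalid alignments (ragged lengths, bad states)."""


class InputError(ValueError):
    """Raised for unreadable, empty, or internally inconsistent input files."""


@dataclass(frozen=True)
class Alignment:
    """An aligned set of equal-length nucleotide sequences.

    Parameters
    ----------
    ids
        Sequence identifiers, unique, in file order.
    seqs
        Upper-case sequences over the alphabet ``ACGTN-``, all of equal length.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in number")
        if len(self.ids) == 0:
            raise InputError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(
                f"unequal sequence lengths: {sorted(lengths)}"
            )
        if self.length < 1:
            raise AlignmentError("alignment length must be >= 1")
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"sequence {sid!r} contains invalid characters {sorted(bad)}"
                )

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        ids, seqs = [], []
        for sid, seq in records:
            ids.append(str(sid))
            seqs.append(str(seq).upper())
        return cls(tuple(ids), tuple(seqs))

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def matrix(self) -> np.ndarray:
        """Return the alignment as an (n, L) uint8 matrix of ASCII codes."""
        return np.frombuffer(
            "".join(self.seqs).encode("ascii"), dtype=np.uint8
        ).reshape(self.n, self.length)

    def retained_columns(self, site_policy: str = COMPLETE_DELETION) -> np.ndarray:
        """Boolean mask of columns kept under the given site policy."""
        mat = self.matrix()
        if site_policy == STRICT:
            return np.ones(self.length, dtype=bool)
        if site_policy == COMPLETE_DELETION:
            drop = (mat == ord("-")) | (mat == ord("N"))
            return ~drop.any(axis=0)
        raise ValueError(f"unknown site policy {site_policy!r}")

    def retained_matrix(self, site_policy: str = COMPLETE_DELETION) -> np.ndarray:
        """Alignment matrix restricted to retained columns.

        Raises
        ------
        InputError
            If complete deletion removes every column.
        """
        mask = self.retained_columns(site_policy)
        if not mask.any():
            raise InputError(
                "every column contains a gap or N; nothing retained "
                "under complete deletion"
            )
        return self.matrix()[:, mask]

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = list(ids)
        index = {sid: i for i, sid in enumerate(self.ids)}
        missing = [sid for sid in wanted if sid not in index]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        return Alignment(
            tuple(wanted), tuple(self.seqs[index[sid]] for sid in wanted)
        )


@dataclass(frozen=True)
class PopulationMap:
    """Maps each sequence id to (locality, haplogroup).

    Every locality belongs to exactly one haplogroup; the constructor
    rejects maps violating that.
    """

    assignments: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        loc2grp: dict[str, str] = {}
        for sid, (loc, grp) in self.assignments.items():
            if loc in loc2grp and loc2grp[loc] != grp:
                raise InputError(
                    f"locality {loc!r} assigned to both {loc2grp[loc]!r} "
                    f"and {grp!r}"
                )
            loc2grp[loc] = grp

    @property
    def haplogroups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, (_, grp) in self.assignments.items():
            seen.setdefault(grp)
        return tuple(seen)

    def group_of(self, sid: str) -> str:
        return self.assignments[sid][1]

    def ids_in_group(self, group: str) -> tuple[str, ...]:
        if group not in self.haplogroups:
            raise KeyError(f"unknown haplogroup {group!r}")
        return tuple(
            sid for sid, (_, grp) in self.assignments.items() if grp == group
        )

    @classmethod
    def read(cls, path: str | Path) -> "PopulationMap":
        """Read a 3-column TSV (id, locality, haplogroup) with header."""
        assignments: dict[str, tuple[str, str]] = {}
        lines = Path(path).read_text().splitlines()
        if not lines:
            raise InputError(f"empty population map: {path}")
        for line in lines[1:]:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise InputError(f"malformed population-map line: {line!r}")
            sid, loc, grp = parts[0], parts[1], parts[2]
            if sid in assignments:
                raise InputError(f"duplicate id in population map: {sid!r}")
            assignments[sid] = (loc, grp)
        return cls(assignments)

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\tlocality\thaplogroup\n")
            for sid, (loc, grp) in self.assignments.items():
                fh.write(f"{sid}\t{loc}\t{grp}\n")


_HAP_TOKEN = re.compile(r"^\s*(?P<label>[A-Za-z0-9_.-]+?)\s*(?:\(\s*(?P<count>\d+)\s*\))?\s*$")


@dataclass
class HaplotypeTable:
    """Locality x haplotype count table with haplogroup labels.

    ``rows`` maps locality code -> (haplogroup, {haplotype label: count}).
    ``declared_n`` optionally records a per-locality sample size stated in
    the source table; when present it is authoritative for totals, and any
    disagreement with the token sum is listed in ``inconsistencies``.
    """

    rows: dict[str, tuple[str, dict[str, int]]] = field(default_factory=dict)
    declared_n: dict[str, int] = field(default_factory=dict)

    def add_row(
        self,
        locality: str,
        haplogroup: str,
        counts: dict[str, int],
        declared_n: int | None = None,
    ) -> None:
        if locality in self.rows:
            raise InputError(f"duplicate locality {locality!r}")
        if any(c < 1 for c in counts.values()):
            raise InputError(f"non-positive haplotype count in {locality!r}")
        self.rows[locality] = (haplogroup, dict(counts))
        if declared_n is not None:
            self.declared_n[locality] = int(declared_n)

    @property
    def inconsistencies(self) -> tuple[tuple[str, int, int], ...]:
        """Rows whose declared n disagrees with the haplotype-count sum,
        as (locality, declared, token_sum)."""
        out = []
        for loc, n in self.declared_n.items():
            s = sum(self.rows[loc][1].values())
            if s != n:
                out.append((loc, n, s))
        return tuple(out)

    @property
    def localities(self) -> tuple[str, ...]:
        return tuple(self.rows)

    @property
    def haplogroups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for grp, _ in self.rows.values():
            seen.setdefault(grp)
        return tuple(seen)

    @property
    def haplotype_labels(self) -> tuple[str, ...]:
        labels: set[str] = set()
        for _, counts in self.rows.values():
            labels.update(counts)
        return tuple(sorted(labels))

    def locality_total(self, locality: str) -> int:
        if locality in self.declared_n:
            return self.declared_n[locality]
        return sum(self.rows[locality][1].values())

    def group_total(self, group: str) -> int:
        return sum(
            self.locality_total(loc)
            for loc, (grp, _) in self.rows.items()
            if grp == group
        )

    @property
    def grand_total(self) -> int:
        return sum(self.locality_total(loc) for loc in self.rows)

    def haplotype_counts(self, group: str | None = None) -> dict[str, int]:
        """Pooled haplotype counts, optionally restricted to one haplogroup."""
        pooled: dict[str, int] = {}
        for loc, (grp, counts) in self.rows.items():
            if group is not None and grp != group:
                continue
            for lab, c in counts.items():
                pooled[lab] = pooled.get(lab, 0) + c
        return pooled


def read_alignment(path: str | Path, fmt: str = "fasta") -> Alignment:
    """Read an aligned FASTA into an :class:`Alignment`.

    Raises :class:`InputError` on empty files and :class:`AlignmentError`
    on ragged (unequal-length) records.
    """
    if fmt.lower() != "fasta":
        raise ValueError(f"unsupported alignment format {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return Alignment.from_records(records)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(alignment.ids, alignment.seqs)
    ]
    SeqIO.write(recs, str(path), "fasta")


def collapse_haplotypes(
    alignment: Alignment, site_policy: str = COMPLETE_DELETION
) -> tuple[dict[str, str], dict[str, str]]:
    """Collapse identical sequences into haplotypes.

    Two sequences share a haplotype iff they are identical at all retained
    sites.  Labels are assigned ``H01, H02, ...`` in order of first
    appearance, the DnaSP-style convention.

    Returns
    -------
    (assignment, representatives)
        ``assignment`` maps sequence id -> haplotype label;
        ``representatives`` maps haplotype label -> full-length sequence of
        its first member.
    """
    mat = alignment.retained_matrix(site_policy)
    keys = [bytes(row) for row in mat]
    assignment: dict[str, str] = {}
    representatives: dict[str, str] = {}
    key2label: dict[bytes, str] = {}
    for i, sid in enumerate(alignment.ids):
        key = keys[i]
        if key not in key2label:
            label = f"H{len(key2label) + 1:02d}"
            key2label[key] = label
            representatives[label] = alignment.seqs[i]
        assignment[sid] = key2label[key]
    return assignment, representatives


def parse_haplotype_table(path: str | Path, strict: bool = True) -> HaplotypeTable:
    """Parse a TSV frequency table: locality, haplogroup, [n,] haplotypes.

    The ``haplotypes`` column holds comma-separated ``H##(count)`` tokens; a
    bare token means count 1.  When a declared ``n`` column is present each
    locality total is cross-checked against it: with ``strict=True``
    (default) a disagreement raises :class:`InputError` naming the locality;
    with ``strict=False`` the row is kept, the declared n is treated as
    authoritative for totals, and the disagreement is recorded in
    :attr:`HaplotypeTable.inconsistencies`.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines:
        raise InputError(f"empty haplotype table: {path}")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    try:
        i_loc = header.index("locality")
        i_grp = header.index("haplogroup")
        i_hap = header.index("haplotypes")
    except ValueError as exc:
        raise InputError(f"missing required column in {path}: {exc}") from exc
    i_n = header.index("n") if "n" in header else None

    table = HaplotypeTable()
    for line in lines[1:]:
        parts = line.split("\t")
        loc = parts[i_loc].strip()
        grp = parts[i_grp].strip()
        counts: dict[str, int] = {}
        for token in parts[i_hap].split(","):
            if not token.strip():
                continue
            m = _HAP_TOKEN.match(token)
            if not m:
                raise InputError(f"bad haplotype token {token!r} in {loc!r}")
            lab = m.group("label")
            k = int(m.group("count") or 1)
            if k < 1:
                raise InputError(f"non-positive count for {lab!r} in {loc!r}")
            counts[lab] = counts.get(lab, 0) + k
        declared = int(parts[i_n]) if i_n is not None else None
        table.add_row(loc, grp, counts, declared_n=declared)
        if declared is not None:
            total = sum(counts.values())
            if declared != total and strict:
                raise InputError(
                    f"locality {loc!r}: declared n={declared} but haplotype "
                    f"counts sum to {total}"
                )
    return table


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("locality\thaplogroup\tn\thaplotypes\n")
        for loc, (grp, counts) in table.rows.items():
            toks = ", ".join(
                lab if c == 1 else f"{lab}({c})" for lab, c in counts.items()
            )
            fh.write(f"{loc}\t{grp}\t{table.locality_total(loc)}\t{toks}\n")


def subset_by_group(
    data: Alignment | HaplotypeTable,
    population_map: PopulationMap | None,
    group: str,
):
    """Restrict an alignment or haplotype table to one haplogroup."""
    if isinstance(data, Alignment):
        if population_map is None:
            raise ValueError("subsetting an alignment requires a population map")
        ids = [sid for sid in data.ids if population_map.group_of(sid) == group]
        if group not in population_map.haplogroups:
            raise KeyError(f"unknown haplogroup {group!r}")
        return data.subset(ids)
    if isinstance(data, HaplotypeTable):
        if group not in data.haplogroups:
            raise KeyError(f"unknown haplogroup {group!r}")
        out = HaplotypeTable()
        for loc, (grp, counts) in data.rows.items():
            if grp == group:
                out.add_row(loc, grp, counts, declared_n=data.declared_n.get(loc))
        return out
    raise TypeError(f"cannot subset {type(data).__name__}")


def load_example_table() -> HaplotypeTable:
    """Load the bundled *D. armandi* COI haplotype-frequency table.

    38 collecting localities across four mountain-system haplogroups
    (MSM, QLM, MCM, TPM), 255 individuals, haplotypes H01-H47.  Two source
    rows (Wd, Ld) declare a sample size one below their haplotype-token sum;
    the declared n is used for totals and both rows are listed in
    :attr:`HaplotypeTable.inconsistencies`.
    """
    ref = resources.files("mitopop.data").joinpath("darmandi_coi_table.tsv")
    with resources.as_file(ref) as p:
        return parse_haplotype_table(p, strict=False)
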
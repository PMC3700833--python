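"""Readers, writers and domain containers for every external format the pipeline touches.

All sequence data lives internally on the DNA alphabet (``U`` is normalized to
``T`` on input) so that exact matching uses one canonical alphabet.  Tables are
plain UTF-8 TSV with ``.`` as the decimal separator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReferenceBundle",
    "CountTable",
    "read_fasta",
    "write_fasta",
    "read_count_table",
    "write_count_table",
    "read_ct_table",
    "write_ct_table",
    "read_tag_table",
    "write_tag_table",
    "load_reference_bundle",
    "write_reference_bundle",
    "mirna_base_name",
    "mirna_family",
    "is_star_name",
    "NCRNA_CLASSES",
]

NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "scRNA", "snoRNA")

_VALID_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TOTALS_ROW_ID = "TOTAL_CLEAN_READS"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _normalize_seq(seq: str, *, where: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID_ALPHABET
    if bad:
        raise FormatError(f"invalid characters {sorted(bad)} in sequence of {where}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement on the canonical DNA alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


# --------------------------------------------------------------------------
# miRBase-dialect identifier parsing
# --------------------------------------------------------------------------

_ARM_RE = re.compile(r"-(5p|3p)$")
_FAMILY_RE = re.compile(r"^(?P<fam>(?:miR|let|lin)-\d+)(?P<var>[a-z]*)(?:-\d+)?$", re.IGNORECASE)
_SPECIES_RE = re.compile(r"^[a-z]{3,4}-")


def is_star_name(name: str) -> bool:
    """Legacy ``*`` suffix or an explicit ``-3p`` arm is treated as the minor arm marker."""
    return name.endswith("*")


def mirna_base_name(name: str) -> str:
    """Strip the star marker and arm suffix: ``gga-miR-140*`` and ``gga-miR-140-5p``
    both map to ``gga-miR-140`` so the two arms of one duplex pair up."""
    name = name[:-1] if name.endswith("*") else name
    return _ARM_RE.sub("", name)


def mirna_family(name: str) -> str:
    """Family name: species prefix, arm suffix and trailing letter/locus variants
    removed (``gga-let-7a`` -> ``let-7``, ``gga-miR-30a-5p`` -> ``miR-30``)."""
    base = mirna_base_name(name)
    base = _SPECIES_RE.sub("", base)
    m = _FAMILY_RE.match(base)
    return m.group("fam") if m else base


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path: str | Path, class_tag_rule: str | None = None) -> dict:
    """Read a FASTA file into an ordered ``{identifier: sequence}`` mapping.

    Sequences are uppercased and ``U``-normalized.  With
    ``class_tag_rule="pipe"`` each header must look like ``classname|id`` and
    the result maps ``id -> (classname, sequence)``.

    Raises :class:`FormatError` on an empty file or a duplicate identifier —
    records are never silently dropped or merged.
    """
    path = Path(path)
    out: dict = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        seq = _normalize_seq(str(rec.seq), where=rec.id)
        if class_tag_rule == "pipe":
            if "|" not in rec.id:
                raise FormatError(f"header {rec.id!r} lacks a 'class|id' tag")
            cls, ident = rec.id.split("|", 1)
            if cls not in NCRNA_CLASSES:
                raise FormatError(f"unknown ncRNA class {cls!r} in header {rec.id!r}")
            if ident in out:
                raise FormatError(f"duplicate identifier {ident!r} in {path}")
            out[ident] = (cls, seq)
        else:
            if rec.id in out:
                raise FormatError(f"duplicate identifier {rec.id!r} in {path}")
            out[rec.id] = seq
    if n == 0:
        raise FormatError(f"no FASTA records in {path}")
    return out


def write_fasta(path: str | Path, records: dict, *, width: int = 70) -> None:
    """Write ``{id: seq}`` (or ``{id: (class, seq)}``) as FASTA."""
    with open(path, "w") as fh:
        for ident, val in records.items():
            if isinstance(val, tuple):
                cls, seq = val
                header = f"{cls}|{ident}"
            else:
                header, seq = ident, val
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# Reference bundle
# --------------------------------------------------------------------------

@dataclass
class ReferenceBundle:
    """All reference sequence collections the annotation stage matches against.

    ``mature`` and ``star`` are disjoint ``{id: seq}`` maps; every star entry's
    base name either resolves to a mature entry or is listed in
    ``orphan_stars`` (the minor arm can be sequenced when the mature arm never
    was).  ``hairpin_arms`` gives, per hairpin id, the half-open interval of
    each annotated arm inside the hairpin sequence.
    """

    genome: dict[str, str]
    mature: dict[str, str]
    star: dict[str, str]
    hairpins: dict[str, str] = field(default_factory=dict)
    hairpin_arms: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    ncrna: dict[str, tuple[str, str]] = field(default_factory=dict)
    orphan_stars: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        overlap = set(self.mature) & set(self.star)
        if overlap:
            raise FormatError(f"identifiers listed as both mature and star: {sorted(overlap)}")
        mature_bases = {mirna_base_name(m) for m in self.mature}
        orphans = [s for s in self.star if mirna_base_name(s) not in mature_bases]
        self.orphan_stars = tuple(sorted(orphans))
        for ident, seq in self.mature.items():
            if not 18 <= len(seq) <= 26:
                raise FormatError(f"mature miRNA {ident!r} length {len(seq)} outside 18-26 nt")

    @property
    def all_mirnas(self) -> dict[str, str]:
        return {**self.mature, **self.star}


def load_reference_bundle(directory: str | Path) -> ReferenceBundle:
    """Load ``genome.fa``, ``mature.fa``, ``hairpin.fa`` and ``ncrna.fa`` from a
    directory.  Star arms live in ``mature.fa`` and are recognized by the
    legacy ``*`` suffix or by a ``-3p`` arm whose ``-5p``/bare sibling exists."""
    d = Path(directory)
    genome = read_fasta(d / "genome.fa")
    mirnas = read_fasta(d / "mature.fa")
    hairpins = read_fasta(d / "hairpin.fa") if (d / "hairpin.fa").exists() else {}
    ncrna = read_fasta(d / "ncrna.fa", class_tag_rule="pipe") if (d / "ncrna.fa").exists() else {}

    mature: dict[str, str] = {}
    star: dict[str, str] = {}
    names = set(mirnas)
    for ident, seq in mirnas.items():
        if ident.endswith("*"):
            star[ident] = seq
        elif ident.endswith("-3p") and (
            mirna_base_name(ident) + "-5p" in names or mirna_base_name(ident) in names
        ):
            star[ident] = seq
        else:
            mature[ident] = seq
    arms_path = d / "hairpin_arms.tsv"
    hairpin_arms: dict[str, dict[str, tuple[int, int]]] = {}
    if arms_path.exists():
        arms = pd.read_csv(arms_path, sep="\t")
        for row in arms.itertuples(index=False):
            hairpin_arms.setdefault(row.hairpin, {})[row.arm] = (int(row.start), int(row.end))
    return ReferenceBundle(
        genome=genome, mature=mature, star=star, hairpins=hairpins,
        hairpin_arms=hairpin_arms, ncrna=ncrna,
    )


def write_reference_bundle(bundle: ReferenceBundle, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_fasta(d / "genome.fa", bundle.genome)
    write_fasta(d / "mature.fa", bundle.all_mirnas)
    if bundle.hairpins:
        write_fasta(d / "hairpin.fa", bundle.hairpins)
    if bundle.ncrna:
        write_fasta(d / "ncrna.fa", bundle.ncrna)
    if bundle.hairpin_arms:
        rows = [
            {"hairpin": hp, "arm": arm, "start": iv[0], "end": iv[1]}
            for hp, arms in bundle.hairpin_arms.items()
            for arm, iv in arms.items()
        ]
        pd.DataFrame(rows).to_csv(d / "hairpin_arms.tsv", sep="\t", index=False)


# --------------------------------------------------------------------------
# Count tables
# --------------------------------------------------------------------------

@dataclass
class CountTable:
    """Per-miRNA raw read counts for the two libraries plus their clean-read totals.

    ``counts`` is indexed by miRNA identifier with one integer column per
    library; ``totals`` maps library name to its clean-read total (the
    denominator of normalized expression).
    """

    counts: pd.DataFrame
    totals: dict[str, int]

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.totals):
            raise FormatError(
                f"count columns {list(self.counts.columns)} do not match totals "
                f"{list(self.totals)}"
            )
        if len(self.totals) != 2:
            raise FormatError("a count table names exactly two libraries")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative read count")
        for lib, total in self.totals.items():
            total = int(total)
            if total <= 0:
                raise FormatError(f"non-positive clean-read total for library {lib!r}")
            if int(self.counts[lib].sum()) > total:
                raise FormatError(
                    f"counts in library {lib!r} sum to {int(self.counts[lib].sum())}, "
                    f"above the stated clean total {total}"
                )
        self.totals = {k: int(v) for k, v in self.totals.items()}
        self.counts = self.counts.astype("int64")

    @property
    def libraries(self) -> tuple[str, str]:
        a, b = self.totals
        return a, b


def read_count_table(path: str | Path) -> CountTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] != 3:
        raise FormatError("count table needs exactly three columns: mirna and two libraries")
    id_col = df.columns[0]
    df = df.set_index(id_col)
    if TOTALS_ROW_ID not in df.index:
        raise FormatError(f"totals row {TOTALS_ROW_ID!r} missing")
    totals_row = df.loc[TOTALS_ROW_ID]
    counts = df.drop(index=TOTALS_ROW_ID)
    if counts.index.has_duplicates:
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate miRNA rows: {dupes}")
    try:
        counts = counts.astype("int64")
    except ValueError as exc:
        raise FormatError(f"non-integer count in {path}: {exc}") from exc
    totals = {lib: int(totals_row[lib]) for lib in counts.columns}
    return CountTable(counts=counts, totals=totals)


def write_count_table(table: CountTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.loc[TOTALS_ROW_ID] = [table.totals[c] for c in out.columns]
    out.index.name = "mirna"
    out.to_csv(path, sep="\t")


# --------------------------------------------------------------------------
# Tag tables (collapsed unique reads)
# --------------------------------------------------------------------------

def write_tag_table(tags: dict[str, int], path: str | Path) -> None:
    df = pd.DataFrame(
        {"tag": list(tags), "length": [len(t) for t in tags], "count": list(tags.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def read_tag_table(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"tag": str, "count": "int64"})
    if df["count"].lt(0).any():
        raise FormatError("negative tag count")
    if df["tag"].duplicated().any():
        raise FormatError("duplicate tag rows")
    return dict(zip(df["tag"].map(lambda s: _normalize_seq(s, where="tag table")), df["count"]))


# --------------------------------------------------------------------------
# Ct tables (qPCR)
# --------------------------------------------------------------------------

CT_COLUMNS = ("group", "replicate", "assay", "ct")


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"Ct table missing columns {sorted(missing)}")
    bad = set(df["assay"].unique()) - {"target", "reference"}
    if bad:
        raise FormatError(f"unknown assay labels {sorted(bad)}")
    wide = df.pivot_table(index=["group", "replicate"], columns="assay", values="ct", aggfunc="size")
    for assay in ("target", "reference"):
        if assay not in wide.columns or wide[assay].isna().any() or (wide[assay] != 1).any():
            missing_at = (
                wide.index[wide.get(assay, pd.Series(index=wide.index)).isna()].tolist()
                if assay in wide.columns else wide.index.tolist()
            )
            raise FormatError(f"missing or duplicated {assay!r} Ct for {missing_at}")
    reps = df.groupby("group")["replicate"].nunique()
    if (reps < 2).any():
        raise FormatError(f"fewer than 2 replicates in groups {reps[reps < 2].index.tolist()}")
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"group": str, "assay": str})
    return validate_ct_table(df)


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, CT_COLUMNS].to_csv(path, sep="\t", index=False)
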
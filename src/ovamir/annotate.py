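"""Exact-match hierarchical annotation of unique tags against the reference.

Only perfect matches count as conserved miRNAs, so exact substring matching
stands in for alignment: the retained assignments are identical and the
procedure is deterministic.  A tag gets exactly one category under a fixed
priority — miRNA (mature/star equality, or a hairpin substring confined to an
annotated arm) > the five ncRNA classes > genome-only > unmatched — which
makes the per-library category totals an exact partition of the clean reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .io import CountTable, ReferenceBundle, mirna_base_name, NCRNA_CLASSES
from .preprocess import CleanLibrary, MIN_LEN, MAX_LEN

__all__ = [
    "Assignment",
    "AnnotationResult",
    "TagIndex",
    "classify_tag",
    "quantify_mirnas",
    "category_proportions",
    "proportions_from_totals",
    "arm_report",
    "round_half_up",
    "CATEGORIES",
]

CATEGORIES = ("miRNA",) + NCRNA_CLASSES + ("genome_only", "unmatched")


@dataclass(frozen=True)
class Assignment:
    category: str
    mirna: str | None = None  # identifier, for category == "miRNA"
    arm: str | None = None    # "mature" | "star"


class MultiHitWarning(UserWarning):
    """A tag matched more than one miRNA; the lexicographically smallest id won."""


class TagIndex:
    """Precomputed exact-match lookups for one reference bundle.

    miRNA hits are resolved by (a) equality with a mature or star sequence and
    (b) substring-of-hairpin occurrences whose interval is contained in an
    annotated arm; ncRNA hits enumerate every 18-30 nt window of each class
    sequence; genome hits use a single concatenated text with separators.
    """

    def __init__(self, bundle: ReferenceBundle):
        self.bundle = bundle
        self.mirna_exact: dict[str, list[tuple[str, str]]] = {}
        for ident, seq in bundle.mature.items():
            self.mirna_exact.setdefault(seq, []).append((ident, "mature"))
        for ident, seq in bundle.star.items():
            self.mirna_exact.setdefault(seq, []).append((ident, "star"))
        # hairpin windows confined to an annotated arm, keyed by sequence
        self.arm_windows: dict[str, list[tuple[str, str]]] = {}
        for hp_name, hp_seq in bundle.hairpins.items():
            arms = bundle.hairpin_arms.get(hp_name, {})
            for arm, (lo, hi) in arms.items():
                owner = self._arm_owner(hp_name, arm)
                if owner is None:
                    continue
                for a in range(lo, hi):
                    for length in range(MIN_LEN, min(MAX_LEN, hi - a) + 1):
                        window = hp_seq[a : a + length]
                        hits = self.arm_windows.setdefault(window, [])
                        if (owner, arm) not in hits:
                            hits.append((owner, arm))
        self.ncrna_windows: dict[str, str] = {}
        order = {cls: i for i, cls in enumerate(NCRNA_CLASSES)}
        for _ident, (cls, seq) in sorted(
            bundle.ncrna.items(), key=lambda kv: order[kv[1][0]]
        ):
            for a in range(len(seq)):
                for length in range(MIN_LEN, min(MAX_LEN, len(seq) - a) + 1):
                    self.ncrna_windows.setdefault(seq[a : a + length], cls)
        self.genome_text = "#".join(bundle.genome.values())
        self._arm_owner_cache: dict[tuple[str, str], str | None] = {}

    def _arm_owner(self, hp_name: str, arm: str) -> str | None:
        """Map a hairpin arm back to the miRNA identifier it encodes."""
        arms = self.bundle.hairpin_arms.get(hp_name, {})
        lo, hi = arms[arm]
        seq = self.bundle.hairpins[hp_name][lo:hi]
        table = self.bundle.mature if arm == "mature" else self.bundle.star
        owners = sorted(ident for ident, s in table.items() if s == seq)
        return owners[0] if owners else None


def classify_tag(tag: str, bundle: ReferenceBundle, index: TagIndex | None = None) -> Assignment:
    """Assign one category to a tag (miRNA > ncRNA classes > genome > unmatched).

    Ties among miRNA hits go to the lexicographically smallest identifier with
    a :class:`MultiHitWarning`.
    """
    if index is None:
        index = TagIndex(bundle)
    hits = index.mirna_exact.get(tag) or index.arm_windows.get(tag)
    if hits:
        if len(hits) > 1:
            warnings.warn(
                f"tag matches multiple miRNAs {sorted(h[0] for h in hits)}; "
                "assigning the lexicographically smallest",
                MultiHitWarning,
                stacklevel=2,
            )
        ident, arm = min(hits)
        return Assignment(category="miRNA", mirna=ident, arm=arm)
    cls = index.ncrna_windows.get(tag)
    if cls is not None:
        return Assignment(category=cls)
    if tag in index.genome_text:
        return Assignment(category="genome_only")
    return Assignment(category="unmatched")


@dataclass
class AnnotationResult:
    """Per-tag assignments, per-category read totals and the miRNA count table."""

    assignments: dict[str, Assignment]
    category_totals: pd.DataFrame  # index category, one column per library
    mirna_counts: CountTable
    clean_totals: dict[str, int]
    arms: dict[str, str] = field(default_factory=dict)  # miRNA id -> arm

    @property
    def coexpressed(self) -> list[str]:
        c = self.mirna_counts.counts
        return c.index[(c > 0).all(axis=1)].tolist()


def quantify_mirnas(
    lib_a: CleanLibrary, lib_b: CleanLibrary, bundle: ReferenceBundle
) -> AnnotationResult:
    """Classify the union of tags once and aggregate reads per category and per
    miRNA identifier for both libraries."""
    if not bundle.mature and not bundle.star:
        raise ValueError("reference bundle contains no miRNAs")
    index = TagIndex(bundle)
    libs = {lib_a.name or "A": lib_a, lib_b.name or "B": lib_b}
    if len(libs) != 2:
        raise ValueError("the two libraries need distinct names")
    assignments: dict[str, Assignment] = {}
    for tag in set(lib_a.tags) | set(lib_b.tags):
        assignments[tag] = classify_tag(tag, bundle, index)

    cat_totals = pd.DataFrame(0, index=list(CATEGORIES), columns=list(libs), dtype="int64")
    mirna_rows: dict[str, dict[str, int]] = {}
    arms: dict[str, str] = {}
    for name, lib in libs.items():
        for tag, count in lib.tags.items():
            a = assignments[tag]
            cat_totals.loc[a.category, name] += count
            if a.category == "miRNA":
                mirna_rows.setdefault(a.mirna, dict.fromkeys(libs, 0))[name] += count
                arms[a.mirna] = a.arm
    counts = pd.DataFrame.from_dict(mirna_rows, orient="index").fillna(0).astype("int64")
    counts = counts.reindex(columns=list(libs)).sort_index()
    counts.index.name = "mirna"
    clean_totals = {name: lib.clean_total for name, lib in libs.items()}
    mirna_counts = CountTable(counts=counts, totals=dict(clean_totals))
    return AnnotationResult(
        assignments=assignments,
        category_totals=cat_totals,
        mirna_counts=mirna_counts,
        clean_totals=clean_totals,
        arms=arms,
    )


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding used for printed percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def proportions_from_totals(
    category_totals: pd.DataFrame, clean_totals: dict[str, int]
) -> pd.DataFrame:
    """Percentage of clean reads per category per library (half-up, 2 decimals),
    plus the genome-mapped percentage 100*(clean - unmatched)/clean.
    Categories absent from ``category_totals`` count as zero reads."""
    out = {}
    for lib, clean in clean_totals.items():
        clean = int(clean)
        if clean <= 0:
            raise ValueError(f"zero clean total for library {lib!r}")
        col = {}
        for cat in CATEGORIES:
            reads = int(category_totals.loc[cat, lib]) if cat in category_totals.index else 0
            col[cat] = round_half_up(100.0 * reads / clean)
        unmatched = (
            int(category_totals.loc["unmatched", lib])
            if "unmatched" in category_totals.index
            else 0
        )
        col["genome_mapped"] = round_half_up(100.0 * (clean - unmatched) / clean)
        out[lib] = col
    df = pd.DataFrame(out)
    df.index.name = "category"
    return df


def category_proportions(result: AnnotationResult) -> pd.DataFrame:
    """Per-category percentages of clean reads for an annotation result."""
    return proportions_from_totals(result.category_totals, result.clean_totals)


@dataclass
class ArmReport:
    """Mature vs star arm read counts per duplex, with star-dominance calls."""

    pairs: pd.DataFrame        # index base name; mature/star counts per library
    orphan_stars: pd.DataFrame  # star observed with no mature counterpart


def arm_report(result: AnnotationResult) -> ArmReport:
    """Pair mature/star rows by base name; a duplex is star-dominant only when
    the star arm out-reads the mature arm in both libraries."""
    counts = result.mirna_counts.counts
    if counts.empty:
        raise ValueError("no miRNA counts to report arms for")
    libs = list(counts.columns)
    mature_of: dict[str, str] = {}
    star_of: dict[str, str] = {}
    for ident in counts.index:
        base = mirna_base_name(ident)
        if result.arms.get(ident) == "star":
            star_of[base] = ident
        else:
            mature_of[base] = ident
    rows, orphans = [], []
    for base, star_id in sorted(star_of.items()):
        srow = counts.loc[star_id]
        if base in mature_of:
            mrow = counts.loc[mature_of[base]]
            rec = {"base": base, "mature_id": mature_of[base], "star_id": star_id}
            for lib in libs:
                rec[f"mature_{lib}"] = int(mrow[lib])
                rec[f"star_{lib}"] = int(srow[lib])
            rec["star_dominant"] = all(int(srow[lib]) > int(mrow[lib]) for lib in libs)
            rows.append(rec)
        else:
            orphans.append(
                {"base": base, "star_id": star_id, **{f"star_{lib}": int(srow[lib]) for lib in libs}}
            )
    pairs = pd.DataFrame(rows).set_index("base") if rows else pd.DataFrame()
    orphan_df = pd.DataFrame(orphans).set_index("base") if orphans else pd.DataFrame()
    return ArmReport(pairs=pairs, orphan_stars=orphan_df)
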
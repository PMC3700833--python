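"""Synthetic two-condition small-RNA study generator with known ground truth.

The generator emulates the structure of a pooled two-library ovary small-RNA
experiment: a skewed (log-normal) miRNA abundance distribution, mature >> star
arm ratios with occasional inversions, ncRNA and unannotated contamination, an
insert-length law peaked at 22 nt, and a designated subset of miRNAs carrying a
true log2 fold-change between conditions.  Counts are negative-binomial so the
behavior of the two-library exact test can be probed under the overdispersion
that pooling biological material induces; ``dispersion=0`` gives the Poisson
counts the test actually assumes.

Every output is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountTable, ReferenceBundle, revcomp, NCRNA_CLASSES

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "build_reference",
    "simulate_truth",
    "simulate_counts",
    "simulate_reads",
    "simulate_ct_table",
    "DEFAULT_LENGTH_LAW",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Insert-length law over the 18-30 nt analysis window, mass ranked 22 > 23 > 21
# to mirror the size profile of Dicer products in ovary libraries.
DEFAULT_LENGTH_LAW: dict[int, float] = {
    18: 0.02, 19: 0.03, 20: 0.07, 21: 0.12, 22: 0.30, 23: 0.18,
    24: 0.10, 25: 0.06, 26: 0.04, 27: 0.03, 28: 0.02, 29: 0.02, 30: 0.01,
}

# Contamination shares of clean reads; the miRNA share is the complement.
# Chosen so roughly 70% of clean reads map to the synthetic genome, with the
# miRNA-similar fraction in the ~35% range seen in ovary libraries.
DEFAULT_CONTAMINATION: dict[str, float] = {
    "rRNA": 0.12, "tRNA": 0.08, "snRNA": 0.02, "scRNA": 0.01,
    "snoRNA": 0.04, "unannotated": 0.38,
}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated two-library experiment.

    ``abundance_sigma_log`` is the log-scale standard deviation of the
    log-normal base-abundance law (2.5 spans roughly five orders of magnitude
    across a few hundred miRNAs, reproducing the <20 to >10^6 read range).
    ``effect_min``/``effect_max`` bound |true log2 fold-change| for the
    ``de_fraction`` of miRNAs that are truly differential; the default minimum
    of 1 keeps every planted truth callable at the |log2 ratio| >= 1 threshold.
    ``dispersion`` is the negative-binomial phi in var = mu + phi*mu^2.
    """

    n_mirnas: int = 300
    abundance_mean_log: float = 0.0
    abundance_sigma_log: float = 2.5
    de_fraction: float = 0.10
    effect_min: float = 1.0
    effect_max: float = 4.0
    star_ratio_log_mean: float = math.log(0.03)
    star_ratio_log_sd: float = 1.0
    arm_inversion_prob: float = 0.02
    mirna_fraction: float = 0.35
    contamination: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CONTAMINATION))
    genome_share_of_unannotated: float = 0.20
    library_sizes: tuple[int, int] = (1_000_000, 1_000_000)
    library_names: tuple[str, str] = ("immature_42d", "mature_162d")
    length_law: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_LENGTH_LAW))
    adapter: str = "TCGTATGCCGTC"
    read_length: int = 42
    dispersion: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be >= 1")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.effect_min < 0 or self.effect_max < self.effect_min:
            raise ValueError("need 0 <= effect_min <= effect_max")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        total = self.mirna_fraction + sum(self.contamination.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"miRNA fraction plus contamination proportions must sum to 1, got {total}"
            )
        if any(v < 0 for v in self.contamination.values()):
            raise ValueError("contamination proportions must be non-negative")
        law = sum(self.length_law.values())
        if abs(law - 1.0) > 1e-9:
            raise ValueError(f"length law masses sum to {law}, not 1")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthTable:
    """Ground truth for recovery testing: per-miRNA base abundance (relative
    weight), true log2 fold-change of the second library over the first (0 for
    non-DE rows), and star:mature arm ratio."""

    per_mirna: pd.DataFrame  # index mirna; columns base_weight, true_log2fc, star_ratio
    library_sizes: dict[str, int]

    @property
    def de_mirnas(self) -> list[str]:
        t = self.per_mirna
        return t.index[t["true_log2fc"] != 0.0].tolist()


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mirna_names(n: int) -> list[str]:
    """Deterministic miRBase-dialect names; the first few form a let-7-style
    lettered family so family collapsing is exercised."""
    names: list[str] = []
    n_family = min(3, n) if n >= 5 else 0
    for i in range(n_family):
        names.append(f"gga-let-7{chr(ord('a') + i)}")
    for i in range(n - n_family):
        names.append(f"gga-miR-{100 + i}")
    return names


def build_reference(config: SimulationConfig) -> ReferenceBundle:
    """Construct a self-consistent reference bundle.

    Each mature miRNA is embedded verbatim in its hairpin (5' arm) and that
    hairpin in exactly one genome record; the star arm is the reverse
    complement of the mature arm (the 3' side of the fold-back).  A handful of
    miRNA-free ``scaffold`` records provide genome-only territory, and each
    ncRNA class gets a few long sequences contaminant reads are cut from.
    """
    if config.n_mirnas > 4 ** 10:
        raise ValueError("n_mirnas exhausts the sequence space at miRNA lengths")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    names = _mirna_names(config.n_mirnas)

    for _attempt in range(20):
        seen: set[str] = set()
        mature: dict[str, str] = {}
        star: dict[str, str] = {}
        hairpins: dict[str, str] = {}
        hairpin_arms: dict[str, dict[str, tuple[int, int]]] = {}
        genome: dict[str, str] = {}
        ok = True
        for i, name in enumerate(names):
            for _ in range(50):
                length = int(rng.choice([21, 22, 23], p=[0.15, 0.70, 0.15]))
                seq = _rand_seq(rng, length)
                sseq = revcomp(seq)
                if seq not in seen and sseq not in seen and seq != sseq:
                    break
            else:
                ok = False
                break
            seen.add(seq)
            seen.add(sseq)
            mature[name] = seq
            # alternate between the legacy "*" and the "-3p" star dialects
            star_name = f"{name}*" if i % 2 == 0 else f"{name}-3p"
            star[star_name] = sseq
            loop = _rand_seq(rng, int(rng.integers(8, 13)))
            hp = seq + loop + sseq
            hp_name = name.replace("miR", "mir") + "-hp"
            hairpins[hp_name] = hp
            hairpin_arms[hp_name] = {
                "mature": (0, len(seq)),
                "star": (len(seq) + len(loop), len(hp)),
            }
            genome[f"chr{i + 1}"] = _rand_seq(rng, 30) + hp + _rand_seq(rng, 30)
        if not ok:
            continue

        n_scaffolds = max(2, config.n_mirnas // 50)
        for j in range(n_scaffolds):
            genome[f"scaffold{j + 1}"] = _rand_seq(rng, 300)
        ncrna: dict[str, tuple[str, str]] = {}
        for cls in NCRNA_CLASSES:
            for k in range(3):
                ncrna[f"{cls}_{k + 1}"] = (cls, _rand_seq(rng, 120))

        # reject the (vanishingly unlikely) build where a miRNA arm strays into
        # contaminant or off-target genome territory
        genome_cat = "#".join(genome.values())
        ncrna_cat = "#".join(s for _, s in ncrna.values())
        clean = True
        for seq in list(mature.values()) + list(star.values()):
            if seq in ncrna_cat or genome_cat.count(seq) != 1:
                clean = False
                break
        if clean:
            return ReferenceBundle(
                genome=genome, mature=mature, star=star, hairpins=hairpins,
                hairpin_arms=hairpin_arms, ncrna=ncrna,
            )
    raise RuntimeError("could not build a collision-free reference bundle")


def simulate_truth(config: SimulationConfig) -> TruthTable:
    """Draw base abundances, the DE subset with its true effects, and arm ratios."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 202]))
    names = _mirna_names(config.n_mirnas)
    weights = rng.lognormal(config.abundance_mean_log, config.abundance_sigma_log, config.n_mirnas)
    n_de = int(round(config.de_fraction * config.n_mirnas))
    de_idx = rng.choice(config.n_mirnas, size=n_de, replace=False)
    effects = np.zeros(config.n_mirnas)
    magnitudes = rng.uniform(config.effect_min, config.effect_max, n_de)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effects[de_idx] = magnitudes * signs
    ratios = np.exp(rng.normal(config.star_ratio_log_mean, config.star_ratio_log_sd, config.n_mirnas))
    ratios = np.minimum(ratios, 0.8)
    # occasional arm inversion: the minor arm out-reads the mature arm by a
    # bounded factor (the miR-140-like pattern)
    inverted = rng.random(config.n_mirnas) < config.arm_inversion_prob
    ratios[inverted] = rng.uniform(2.0, 15.0, int(inverted.sum()))
    # expected null NE of the mature arm, with the miRNA budget shared over
    # mature + star mass so the configured miRNA fraction is hit exactly
    mature_share = weights / (weights * (1.0 + ratios)).sum()
    base_ne = 1e6 * config.mirna_fraction * mature_share
    per = pd.DataFrame(
        {
            "base_weight": weights,
            "true_log2fc": effects,
            "star_ratio": ratios,
            "base_ne": base_ne,
        },
        index=pd.Index(names, name="mirna"),
    )
    sizes = dict(zip(config.library_names, (int(s) for s in config.library_sizes)))
    return TruthTable(per_mirna=per, library_sizes=sizes)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0.0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(config: SimulationConfig, truth: TruthTable) -> CountTable:
    """Draw the two-library miRNA count table implied by the truth table.

    A true log2 fold-change f (second library over first) is split
    symmetrically, x2^(-f/2) on the first library and x2^(+f/2) on the second,
    so total library composition stays comparable.  Star-arm rows are included
    with means scaled by the truth's arm ratio.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 303]))
    per = truth.per_mirna
    ratio = per["star_ratio"].to_numpy()
    w = per["base_weight"].to_numpy()
    share = w / (w * (1.0 + ratio)).sum()  # mature share of the miRNA budget
    lib_a, lib_b = config.library_names
    size_a = truth.library_sizes[lib_a]
    size_b = truth.library_sizes[lib_b]
    f = per["true_log2fc"].to_numpy()
    mean_a = size_a * config.mirna_fraction * share * np.exp2(-f / 2.0)
    mean_b = size_b * config.mirna_fraction * share * np.exp2(+f / 2.0)

    names = _mirna_names(config.n_mirnas)
    star_names = [f"{n}*" if i % 2 == 0 else f"{n}-3p" for i, n in enumerate(names)]
    counts = pd.DataFrame(
        {
            lib_a: np.concatenate([_nb_draw(rng, mean_a, config.dispersion),
                                   _nb_draw(rng, mean_a * ratio, config.dispersion)]),
            lib_b: np.concatenate([_nb_draw(rng, mean_b, config.dispersion),
                                   _nb_draw(rng, mean_b * ratio, config.dispersion)]),
        },
        index=pd.Index(names + star_names, name="mirna"),
    )
    totals = {lib_a: size_a, lib_b: size_b}
    return CountTable(counts=counts, totals=totals)


def _length_draws(rng: np.random.Generator, law: dict[int, float], n: int) -> np.ndarray:
    lengths = np.array(sorted(law))
    probs = np.array([law[k] for k in lengths], dtype=float)
    return rng.choice(lengths, size=n, p=probs)


def _contaminant_inserts(
    rng: np.random.Generator,
    config: SimulationConfig,
    bundle: ReferenceBundle,
    n_by_class: dict[str, int],
) -> list[str]:
    """Cut contaminant inserts: ncRNA-class reads are random windows of that
    class's sequences; 'unannotated' reads split between scaffold windows
    (genome-only) and a fixed pool of reference-free sequences (unmatched)."""
    inserts: list[str] = []
    by_class: dict[str, list[str]] = {
        cls: [seq for c, seq in bundle.ncrna.values() if c == cls] for cls in NCRNA_CLASSES
    }
    scaffolds = [seq for name, seq in bundle.genome.items() if name.startswith("scaffold")]
    pool = [
        _rand_seq(rng, int(length))
        for length in _length_draws(rng, config.length_law, 200)
    ]
    for cls, n in n_by_class.items():
        if n <= 0:
            continue
        if cls == "unannotated":
            n_genome = int(round(n * config.genome_share_of_unannotated))
            lengths = _length_draws(rng, config.length_law, n_genome)
            for length in lengths:
                src = scaffolds[int(rng.integers(len(scaffolds)))]
                start = int(rng.integers(0, len(src) - int(length) + 1))
                inserts.append(src[start : start + int(length)])
            idx = rng.integers(0, len(pool), size=n - n_genome)
            inserts.extend(pool[i] for i in idx)
        else:
            sources = by_class[cls]
            lengths = _length_draws(rng, config.length_law, n)
            for length in lengths:
                src = sources[int(rng.integers(len(sources)))]
                start = int(rng.integers(0, len(src) - int(length) + 1))
                inserts.append(src[start : start + int(length)])
    return inserts


def simulate_reads(
    config: SimulationConfig,
    bundle: ReferenceBundle,
    counts: CountTable,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit one FASTQ per library: each read is insert + 3' adapter truncated
    to the read length, constant quality 'I'.  The per-miRNA read multiset
    matches ``counts`` exactly; contaminant reads fill each library up to its
    clean-read total, split across classes by the configured proportions."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 404]))
    seq_of = bundle.all_mirnas
    contam_total_frac = sum(config.contamination.values())
    paths: dict[str, Path] = {}
    for lib in counts.libraries:
        inserts: list[str] = []
        for mirna, n in counts.counts[lib].items():
            if n > 0:
                inserts.extend([seq_of[mirna]] * int(n))
        n_mirna_reads = len(inserts)
        n_other = max(0, counts.totals[lib] - n_mirna_reads)
        fracs = {c: v / contam_total_frac for c, v in config.contamination.items()}
        classes = list(fracs)
        alloc = rng.multinomial(n_other, [fracs[c] for c in classes])
        inserts.extend(
            _contaminant_inserts(rng, config, bundle, dict(zip(classes, alloc)))
        )
        order = rng.permutation(len(inserts))
        path = out_dir / f"{lib}.fastq"
        with open(path, "w") as fh:
            for ridx, i in enumerate(order):
                seq = (inserts[i] + config.adapter)[: config.read_length]
                fh.write(f"@{lib}_{ridx}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths[lib] = path
    return paths


def simulate_ct_table(
    groups: list[str],
    true_relative_expression: dict[str, float],
    replicates: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    reference_baseline: float = 15.0,
    target_offset: float = 8.0,
) -> pd.DataFrame:
    """Simulate a replicate Ct table for one target assay against a reference gene.

    Per replicate, the reference Ct is its baseline plus Gaussian noise and the
    target Ct is that reference Ct plus a fixed offset minus log2(true level)
    plus its own noise — so at zero noise the 2^-ddCt estimate recovers the
    configured levels exactly.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 505]))
    rows = []
    for group in groups:
        level = float(true_relative_expression[group])
        if level <= 0:
            raise ValueError(f"non-positive true level for group {group!r}")
        for rep in range(1, replicates + 1):
            ct_ref = reference_baseline + rng.normal(0.0, noise_sd)
            ct_tgt = ct_ref + target_offset - math.log2(level) + rng.normal(0.0, noise_sd)
            rows.append({"group": group, "replicate": rep, "assay": "reference", "ct": ct_ref})
            rows.append({"group": group, "replicate": rep, "assay": "target", "ct": ct_tgt})
    return pd.DataFrame(rows)
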
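"""Synthetic populations for variation-graph experiments.

This module generates every input the rest of the package consumes:
a reference sequence (optionally carrying dispersed, slightly diverged
repeat families, the main source of read-mapping ambiguity in real
genomes), a multi-population panel of phased biallelic SNPs and short
(< 50 bp) indels with a controllable site-frequency spectrum, windowed
nucleotide diversity, and microarray-like truth genotype subsets.

Coordinates are 0-based half-open throughout; VCF/BED writers in
:mod:`augref.io` convert to the 1-based conventions of those formats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

ALPHABET = np.frombuffer(b"ACGT", dtype="S1")

#: Frequency-class boundaries of the site-frequency-spectrum model.
#: First class is "singleton" (exactly one alternate allele copy in the
#: panel); the remaining classes are alternate-allele-frequency intervals.
SFS_CLASS_BOUNDS: tuple[tuple[float, float], ...] = (
    (0.0, 0.05),
    (0.05, 0.10),
    (0.10, 0.25),
    (0.25, 0.50),
    (0.50, 1.00),
)

#: Default class weights (singleton first), cattle-like: ~14% singletons
#: and roughly a quarter of variants below 5% minor allele frequency.
DEFAULT_SFS = (0.14, 0.16, 0.12, 0.22, 0.20, 0.16)


@dataclass
class RepeatSpec:
    """Dispersed repeat families implanted into a synthetic reference.

    Each family is a random consensus unit copied ``copies`` times at
    random non-overlapping locations; every copy is independently mutated
    at per-base rate ``divergence`` so copies are near- but not fully
    identical, which is what makes short-read placement ambiguous.
    """

    n_families: int = 6
    copies: int = 10
    unit_length: int = 600
    divergence: float = 0.01

    @classmethod
    def for_length(cls, length: int, fraction: float = 0.18,
                   unit_length: int = 600, divergence: float = 0.01) -> "RepeatSpec":
        """Scale the repeat content to roughly ``fraction`` of a genome."""
        unit = min(unit_length, max(100, length // 50))
        total_copies = max(2, int(fraction * length / unit))
        n_fam = max(1, min(6, total_copies // 3))
        return cls(n_fam, max(1, total_copies // n_fam), unit, divergence)


@dataclass
class ReferenceSequence:
    name: str
    sequence: str
    #: (start, end, label) annotation intervals, e.g. implanted repeats.
    features: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError("reference alphabet restricted to ACGT")


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP, insertion or deletion on the reference.

    Indels follow the VCF anchor convention: ref and alt share a leading
    anchor base, so an insertion has ``len(ref) == 1`` and a deletion
    ``len(alt) == 1``.
    """

    chrom: str
    pos: int  # 0-based offset of the first ref base (anchor for indels)
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 0 or not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError(f"malformed variant at {self.pos}")
        if len(self.ref) > 1 and len(self.alt) > 1:
            raise ValueError("only SNPs and simple indels are supported")
        if (len(self.ref) > 1 or len(self.alt) > 1) and self.ref[0] != self.alt[0]:
            raise ValueError("indel alleles must share a leading anchor base")

    @property
    def vclass(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNP"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def length_delta(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def end(self) -> int:
        """End (exclusive) of the reference span."""
        return self.pos + len(self.ref)


class VariantPanel:
    """Phased biallelic variants for one or more populations.

    ``haplotypes`` is a 0/1 matrix of shape (2 * n_samples, n_variants);
    rows 2i and 2i+1 are the two haplotypes of sample i. Allele
    frequencies are always derived from this matrix, never stored
    separately, so they cannot drift out of sync.
    """

    def __init__(
        self,
        variants: list[Variant],
        samples: list[tuple[str, str]],
        haplotypes: np.ndarray,
        ref_length: int | None = None,
        chrom: str = "chrS",
    ) -> None:
        order = sorted(range(len(variants)), key=lambda i: variants[i].pos)
        variants = [variants[i] for i in order]
        haplotypes = np.asarray(haplotypes, dtype=np.int8)
        if haplotypes.shape != (2 * len(samples), len(variants)):
            raise ValueError("haplotype matrix shape mismatch")
        haplotypes = haplotypes[:, order]
        for a, b in zip(variants, variants[1:]):
            if b.pos < a.end:
                raise ValueError(f"overlapping variants at {a.pos}/{b.pos}")
        self.variants = variants
        self.samples = list(samples)
        self.haplotypes = haplotypes
        self.ref_length = ref_length
        self.chrom = chrom
        self.positions = np.array([v.pos for v in variants], dtype=np.int64)

    # -- bookkeeping -------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, pop in self.samples:
            seen.setdefault(pop, None)
        return list(seen)

    def sample_index(self, sample: str) -> int:
        for i, (sid, _) in enumerate(self.samples):
            if sid == sample:
                return i
        raise KeyError(f"unknown sample {sample!r}")

    def hap_rows(self, pop: str | None = None) -> np.ndarray:
        """Row indices of the haplotypes belonging to ``pop`` (all if None)."""
        if pop is None:
            return np.arange(self.haplotypes.shape[0])
        rows = [
            r
            for i, (_, p) in enumerate(self.samples)
            if p == pop
            for r in (2 * i, 2 * i + 1)
        ]
        if not rows:
            raise KeyError(f"unknown population {pop!r}")
        return np.array(rows, dtype=np.int64)

    def af(self, pop: str | None = None) -> np.ndarray:
        """Alternate allele frequency per variant (pooled if pop is None)."""
        rows = self.hap_rows(pop)
        if len(rows) == 0:
            raise ValueError("population has no haplotypes")
        return self.haplotypes[rows].mean(axis=0)

    def alt_count(self, pop: str | None = None) -> np.ndarray:
        return self.haplotypes[self.hap_rows(pop)].sum(axis=0)

    def sample_haplotype(self, sample: str, hap: int) -> np.ndarray:
        """0/1 allele indicators of one haplotype (hap in {1, 2})."""
        if hap not in (1, 2):
            raise ValueError("hap must be 1 or 2")
        return self.haplotypes[2 * self.sample_index(sample) + hap - 1]

    def genotypes(self, sample: str) -> np.ndarray:
        i = self.sample_index(sample)
        return self.haplotypes[2 * i] + self.haplotypes[2 * i + 1]


@dataclass
class TruthGenotypes:
    """Diploid truth genotypes plus a microarray-like site subset."""

    sample: str
    positions: np.ndarray  # all panel positions
    genotypes: np.ndarray  # 0/1/2 alternate-allele dosages
    array_subset: np.ndarray  # indices into positions

    def subset_positions(self) -> np.ndarray:
        return self.positions[self.array_subset]


# ---------------------------------------------------------------------------
# reference generation


def generate_reference(
    length: int,
    gc_content: float = 0.42,
    seed: int = 0,
    name: str = "chrS",
    repeats: RepeatSpec | None = None,
) -> ReferenceSequence:
    """Generate a pseudo-random reference sequence.

    Bases are drawn i.i.d. with the requested GC content. When
    ``repeats`` is given, diverged copies of random repeat-family units
    are implanted at dispersed locations and recorded as ``repeat``
    features; without them the sequence is uniformly random and
    short-read mapping is essentially unambiguous.
    """
    if length < 1:
        raise ValueError("length must be positive")
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p_at = (1.0 - gc_content) / 2.0
    p_gc = gc_content / 2.0
    arr = rng.choice(ALPHABET, size=length, p=[p_at, p_gc, p_gc, p_at])
    features: list[tuple[int, int, str]] = []
    if repeats is not None and repeats.n_families > 0:
        unit = repeats.unit_length
        if unit * repeats.copies * repeats.n_families > 0.8 * length:
            raise ValueError("repeat content exceeds 80% of the sequence")
        taken: list[tuple[int, int]] = []
        for fam in range(repeats.n_families):
            consensus = rng.choice(ALPHABET, size=unit, p=[p_at, p_gc, p_gc, p_at])
            placed = 0
            attempts = 0
            while placed < repeats.copies and attempts < 1000:
                attempts += 1
                start = int(rng.integers(0, length - unit))
                if any(start < e and start + unit > s for s, e in taken):
                    continue
                copy = consensus.copy()
                n_mut = rng.binomial(unit, repeats.divergence)
                if n_mut:
                    sites = rng.choice(unit, size=n_mut, replace=False)
                    copy[sites] = rng.choice(ALPHABET, size=n_mut)
                arr[start : start + unit] = copy
                taken.append((start, start + unit))
                features.append((start, start + unit, "repeat"))
                placed += 1
        features.sort()
    return ReferenceSequence(name, arr.tobytes().decode(), features)


# ---------------------------------------------------------------------------
# population simulation


def _draw_indel_length(rng: np.random.Generator, max_indel: int) -> int:
    # Mixture: mostly short (geometric, mean ~2 bp) with a uniform tail so
    # the length classes the bias analysis stratifies on are populated.
    if rng.random() < 0.7:
        return min(int(rng.geometric(0.45)), max_indel)
    return int(rng.integers(1, max_indel + 1))


def _place_variants(
    ref: ReferenceSequence,
    n_variants: int,
    indel_fraction: float,
    max_indel: int,
    rng: np.random.Generator,
) -> list[Variant]:
    """Non-overlapping variant placement with allele drawing."""
    L = ref.length
    margin = 5
    specs: list[tuple[int, int]] = []  # (span, signed delta)
    for _ in range(n_variants):
        if rng.random() < indel_fraction:
            ln = _draw_indel_length(rng, max_indel)
            if rng.random() < 0.5:
                specs.append((1, ln))  # insertion: anchor only on ref
            else:
                specs.append((1 + ln, -ln))  # deletion: anchor + deleted bases
        else:
            specs.append((1, 0))
    max_span = max((s for s, _ in specs), default=1)
    if L <= 2 * margin + max_span:
        raise ValueError("reference too short for requested variants")
    rng.shuffle(specs)
    placed: list[tuple[int, int, int]] = []  # (pos, span, delta)
    for attempt in range(6):
        cand = np.sort(rng.integers(margin, L - margin - max_span, size=6 * n_variants))
        placed = []
        prev_end = -2
        for p in cand:
            span, delta = specs[len(placed)]
            if p >= prev_end + 2:
                placed.append((int(p), span, delta))
                prev_end = p + span
                if len(placed) == n_variants:
                    break
        if len(placed) == n_variants:
            break
    if len(placed) < n_variants:
        raise ValueError("n_variants exceeds placeable non-overlapping sites")
    variants: list[Variant] = []
    seq = ref.sequence
    for pos, span, delta in placed:
        anchor = seq[pos]
        if delta == 0:
            alts = [b for b in "ACGT" if b != anchor]
            variants.append(Variant(ref.name, pos, anchor, alts[int(rng.integers(3))]))
        elif delta > 0:
            ins = "".join(
                "ACGT"[i] for i in rng.integers(0, 4, size=delta)
            )
            variants.append(Variant(ref.name, pos, anchor, anchor + ins))
        else:
            variants.append(Variant(ref.name, pos, seq[pos : pos + span], anchor))
    return variants


def simulate_population(
    ref: ReferenceSequence,
    pops: list[tuple[str, int]],
    n_variants: int,
    sfs: tuple[float, ...] = DEFAULT_SFS,
    indel_fraction: float = 0.10,
    max_indel: int = 49,
    shared_fraction: float = 0.7,
    class_correlation: float = 0.5,
    seed: int = 0,
) -> VariantPanel:
    """Simulate a phased multi-population variant panel.

    Each variant is assigned an SFS class (first weight = singletons) and,
    for ``shared_fraction`` of the non-singleton variants, a target
    frequency per population drawn within a frequency class; the rest are
    private to one population. Populations are frequency-differentiated:
    a shared variant keeps the same frequency class in every population
    with probability ``class_correlation`` and draws an independent class
    per population otherwise, so a variant common in one population may
    be rare or absent in another, as observed between livestock breeds.
    Carrier haplotypes are drawn without replacement to match the target
    counts, so stored frequencies are the exact column means of the
    haplotype matrix.
    """
    if n_variants < 0:
        raise ValueError("n_variants must be non-negative")
    if not 0 <= indel_fraction <= 1 or not 0 <= shared_fraction <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if not 1 <= max_indel < 50:
        raise ValueError("max_indel must be in [1, 50)")
    weights = np.asarray(sfs, dtype=float)
    if len(weights) != 1 + len(SFS_CLASS_BOUNDS) or weights.sum() <= 0:
        raise ValueError(f"sfs needs {1 + len(SFS_CLASS_BOUNDS)} weights")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    samples = [
        (f"{label}_{i:03d}", label) for label, n in pops for i in range(n)
    ]
    pop_rows = {
        label: np.array(
            [
                r
                for i, (_, p) in enumerate(samples)
                if p == label
                for r in (2 * i, 2 * i + 1)
            ]
        )
        for label, _ in pops
    }
    n_hap_total = 2 * len(samples)
    if n_variants == 0:
        return VariantPanel([], samples, np.zeros((n_hap_total, 0), dtype=np.int8),
                            ref_length=ref.length, chrom=ref.name)
    variants = _place_variants(ref, n_variants, indel_fraction, max_indel, rng)
    H = np.zeros((n_hap_total, n_variants), dtype=np.int8)
    classes = rng.choice(len(weights), size=n_variants, p=weights)
    labels = [label for label, _ in pops]
    for j, cls in enumerate(classes):
        if cls == 0:  # singleton: exactly one alternate copy panel-wide
            row = int(rng.integers(n_hap_total))
            H[row, j] = 1
            continue
        if rng.random() < shared_fraction:
            target_pops = labels
        else:
            target_pops = [labels[int(rng.integers(len(labels)))]]
        nonsingleton_w = weights[1:] / weights[1:].sum()
        total = 0
        for label in target_pops:
            rows = pop_rows[label]
            pop_cls = cls
            if len(target_pops) > 1 and rng.random() >= class_correlation:
                pop_cls = 1 + int(rng.choice(len(nonsingleton_w), p=nonsingleton_w))
            lo, hi = SFS_CLASS_BOUNDS[pop_cls - 1]
            f = rng.uniform(lo, hi)
            count = int(rng.binomial(len(rows), f))
            count = min(count, len(rows))
            if count:
                H[rng.choice(rows, size=count, replace=False), j] = 1
            total += count
        if total == 0:
            # keep the variant polymorphic: promote to two copies in one pop
            rows = pop_rows[target_pops[0]]
            H[rng.choice(rows, size=min(2, len(rows)), replace=False), j] = 1
        elif total == 1:
            # not drawn from the singleton class: add a second carrier
            carrier_pop = next(
                label for label in target_pops if H[pop_rows[label], j].sum()
            )
            rows = pop_rows[carrier_pop]
            free = rows[H[rows, j] == 0]
            if len(free):
                H[free[int(rng.integers(len(free)))], j] = 1
        if H[:, j].all():
            H[int(rng.integers(n_hap_total)), j] = 0  # avoid panel-wide fixation
    return VariantPanel(variants, samples, H, ref_length=ref.length, chrom=ref.name)


# ---------------------------------------------------------------------------
# summary statistics


def windowed_pi(
    panel: VariantPanel,
    pop: str,
    window: int = 10_000,
    seq_length: int | None = None,
):
    """Nucleotide diversity per bp in non-overlapping windows.

    Per-site diversity is the unbiased pairwise heterozygosity
    2 j (n - j) / (n (n - 1)) with j the alternate allele count among the
    n haplotypes of ``pop``; window values are per-site sums divided by
    the window length. Returns a DataFrame with columns (start, pi).
    """
    import pandas as pd

    if window < 1:
        raise ValueError("window must be >= 1")
    rows = panel.hap_rows(pop)
    n = len(rows)
    if n < 2:
        raise ValueError("need at least two haplotypes")
    length = seq_length if seq_length is not None else panel.ref_length
    if length is None:
        raise ValueError("sequence length unknown; pass seq_length")
    j = panel.haplotypes[rows].sum(axis=0).astype(float)
    site_pi = 2.0 * j * (n - j) / (n * (n - 1))
    starts = np.arange(0, length, window)
    idx = np.minimum(panel.positions // window, len(starts) - 1)
    sums = np.zeros(len(starts))
    np.add.at(sums, idx, site_pi)
    widths = np.minimum(starts + window, length) - starts
    return pd.DataFrame({"start": starts, "pi": sums / widths})


def emulate_truth_sets(
    panel: VariantPanel, sample: str, n_array_sites: int, seed: int = 0
) -> TruthGenotypes:
    """Truth genotypes for one sample plus a random microarray-like subset."""
    gt = panel.genotypes(sample)  # raises KeyError for unknown samples
    if n_array_sites > panel.n_variants:
        raise ValueError("n_array_sites exceeds panel size")
    rng = np.random.default_rng(seed)
    subset = np.sort(rng.choice(panel.n_variants, size=n_array_sites, replace=False))
    return TruthGenotypes(sample, panel.positions.copy(), gt, subset)


def singleton_proportion(panel: VariantPanel) -> float:
    """Fraction of panel variants with exactly one alternate copy."""
    if panel.n_variants == 0:
        return math.nan
    return float((panel.alt_count() == 1).mean())
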
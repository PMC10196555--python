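"""Pooled-amplicon allele-frequency estimation for dual-tagged amplicons.

Each collection site contributes a pool of moth legs.  PCR with site-specific
6-bp tags on both primers yields 216-bp amplicons (6-bp forward tag + 204-bp
genomic fragment + reverse complement of the 6-bp reverse tag), sequenced as
150-bp paired ends.  The pipeline:

1. merge each read pair back into the full amplicon (the overlap must agree
   exactly, otherwise the pair is rejected);
2. demultiplex by exact match of both tags and strip them;
3. collapse identical 204-bp sequences and remove rare ones below the
   theoretical minimum allele frequency ``1/(2n)`` for a pool of ``n`` legs
   (sequencing/PCR error filter);
4. classify surviving reads by the base at the variant offset and report the
   resistant-allele frequency as resistant reads over all surviving reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .stats import Interval, bootstrap_mean_ci

__all__ = [
    "TAG_LENGTH",
    "INSERT_LENGTH",
    "AMPLICON_LENGTH",
    "READ_LENGTH",
    "SitePool",
    "TagScheme",
    "SiteSample",
    "AlleleCounts",
    "SiteFrequency",
    "merge_pair",
    "demultiplex_and_merge",
    "count_alleles",
    "site_frequency",
    "annual_mean_bootstrap",
    "site_frequency_table",
]

TAG_LENGTH = 6
INSERT_LENGTH = 204
AMPLICON_LENGTH = INSERT_LENGTH + 2 * TAG_LENGTH  # 216
READ_LENGTH = 150

_BASES = frozenset("ACGT")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _check_tag(tag: str, what: str) -> str:
    if len(tag) != TAG_LENGTH or set(tag) - _BASES:
        raise ValueError(f"{what} must be a {TAG_LENGTH}-mer over ACGT, got {tag!r}")
    return tag


@dataclass(frozen=True)
class SitePool:
    """One site's pooled sample: its primer tags, pool size, and year."""

    site_id: str
    forward_tag: str
    reverse_tag: str
    n_legs: int
    year: int

    def __post_init__(self) -> None:
        _check_tag(self.forward_tag, "forward_tag")
        _check_tag(self.reverse_tag, "reverse_tag")
        if self.n_legs < 1:
            raise ValueError(f"n_legs must be >= 1, got {self.n_legs}")


class TagScheme:
    """Site-specific dual 6-bp tags, with exact-match lookup.

    Tag pairs must be unique across sites.  The scheme round-trips through a
    CSV with header ``site,forward_tag,reverse_tag,n_legs,year``.
    """

    def __init__(self, pools: Iterable[SitePool]):
        self.pools: dict[str, SitePool] = {}
        self._by_tags: dict[tuple[str, str], str] = {}
        for pool in pools:
            if pool.site_id in self.pools:
                raise ValueError(f"duplicate site_id {pool.site_id!r}")
            key = (pool.forward_tag, pool.reverse_tag)
            if key in self._by_tags:
                raise ValueError(
                    f"tag pair {key} assigned to both "
                    f"{self._by_tags[key]!r} and {pool.site_id!r}"
                )
            self.pools[pool.site_id] = pool
            self._by_tags[key] = pool.site_id
        if not self.pools:
            raise ValueError("tag scheme must contain at least one site")

    def __len__(self) -> int:
        return len(self.pools)

    def __getitem__(self, site_id: str) -> SitePool:
        return self.pools[site_id]

    def site_for_tags(self, forward: str, reverse: str) -> Optional[str]:
        return self._by_tags.get((forward, reverse))

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            [
                {
                    "site": p.site_id,
                    "forward_tag": p.forward_tag,
                    "reverse_tag": p.reverse_tag,
                    "n_legs": p.n_legs,
                    "year": p.year,
                }
                for p in self.pools.values()
            ]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "TagScheme":
        frame = pd.read_csv(path)
        return cls(
            SitePool(
                site_id=str(row.site),
                forward_tag=str(row.forward_tag),
                reverse_tag=str(row.reverse_tag),
                n_legs=int(row.n_legs),
                year=int(row.year),
            )
            for row in frame.itertuples(index=False)
        )


@dataclass
class SiteSample:
    """Merged, tag-stripped amplicon sequences assigned to one site."""

    site_id: str
    year: int
    n_legs: int
    sequences: list[str] = field(default_factory=list)


def merge_pair(
    r1: str, r2: str, amplicon_length: int = AMPLICON_LENGTH
) -> Optional[str]:
    """Reconstruct the amplicon from a read pair, or ``None`` on disagreement.

    R1 is the first ``len(r1)`` bases of the amplicon; R2 is the reverse
    complement of its last ``len(r2)`` bases.  The reconstruction requires the
    overlapping stretch to agree base-for-base.
    """
    r2rc = _revcomp(r2)
    overlap = len(r1) + len(r2) - amplicon_length
    if overlap < 1 or overlap > min(len(r1), len(r2)):
        return None
    if r1[len(r1) - overlap :] != r2rc[:overlap]:
        return None
    return r1 + r2rc[overlap:]


def _fastq_pairs(
    r1: Union[str, Path, Iterable], r2: Union[str, Path, Iterable]
) -> Iterator[tuple[int, str, str]]:
    def records(source):
        if isinstance(source, (str, Path)):
            return SeqIO.parse(str(source), "fastq")
        return iter(source)

    sentinel = object()
    it1, it2 = records(r1), records(r2)
    index = 0
    while True:
        a = next(it1, sentinel)
        b = next(it2, sentinel)
        if a is sentinel and b is sentinel:
            return
        if a is sentinel or b is sentinel:
            raise ValueError(f"unpaired FASTQ input at record index {index}")
        yield index, str(a.seq).upper(), str(b.seq).upper()
        index += 1


def demultiplex_and_merge(
    r1: Union[str, Path, Iterable],
    r2: Union[str, Path, Iterable],
    scheme: TagScheme,
    reference_length: int = INSERT_LENGTH,
) -> tuple[dict[str, SiteSample], int]:
    """Merge read pairs and assign them to sites by exact dual-tag match.

    Returns a mapping ``site_id -> SiteSample`` (every scheme site is present,
    possibly with no sequences) and the count of rejected pairs (failed merge
    or unmatched tags).  Assigned + rejected equals the number of input pairs.
    """
    amplicon_length = reference_length + 2 * TAG_LENGTH
    samples = {
        site_id: SiteSample(site_id=site_id, year=pool.year, n_legs=pool.n_legs)
        for site_id, pool in scheme.pools.items()
    }
    rejected = 0
    for _, seq1, seq2 in _fastq_pairs(r1, r2):
        amplicon = merge_pair(seq1, seq2, amplicon_length)
        if amplicon is None:
            rejected += 1
            continue
        forward = amplicon[:TAG_LENGTH]
        reverse = _revcomp(amplicon[-TAG_LENGTH:])
        site_id = scheme.site_for_tags(forward, reverse)
        if site_id is None:
            rejected += 1
            continue
        samples[site_id].sequences.append(amplicon[TAG_LENGTH:-TAG_LENGTH])
    return samples, rejected


@dataclass(frozen=True)
class AlleleCounts:
    """Allele tallies for one site after the rare-sequence filter."""

    site_id: str
    year: int
    n_legs: int
    r_count: int
    s_count: int
    other_count: int
    n_distinct_surviving: int
    n_reads_input: int
    n_reads_removed: int

    @property
    def total(self) -> int:
        return self.r_count + self.s_count + self.other_count


def count_alleles(
    sample: SiteSample,
    reference: str,
    variant_offset: int,
    resistant_base: str,
    susceptible_base: Optional[str] = None,
) -> AlleleCounts:
    """Collapse identical sequences, apply the ``1/(2n)`` filter, classify.

    Distinct sequences whose frequency among the site's reads is strictly
    below ``1/(2 * n_legs)`` — the smallest allele frequency a pool of
    ``n_legs`` diploid individuals can hold — are removed as likely
    sequencing/PCR errors.  Surviving reads are classified by the base at
    ``variant_offset``: resistant, susceptible (the reference base by
    default), or other.
    """
    if not 0 <= variant_offset < len(reference):
        raise ValueError(
            f"variant_offset {variant_offset} outside reference of length "
            f"{len(reference)}"
        )
    if susceptible_base is None:
        susceptible_base = reference[variant_offset]
    for seq in sample.sequences:
        if len(seq) != len(reference):
            raise ValueError(
                f"site {sample.site_id}: sequence length {len(seq)} does not "
                f"match reference length {len(reference)}"
            )
    counts = Counter(sample.sequences)
    n_input = len(sample.sequences)
    threshold = 1.0 / (2.0 * sample.n_legs)
    surviving = {
        seq: k for seq, k in counts.items() if n_input and k / n_input >= threshold
    }
    removed = n_input - sum(surviving.values())
    r = s = other = 0
    for seq, k in surviving.items():
        base = seq[variant_offset]
        if base == resistant_base:
            r += k
        elif base == susceptible_base:
            s += k
        else:
            other += k
    return AlleleCounts(
        site_id=sample.site_id,
        year=sample.year,
        n_legs=sample.n_legs,
        r_count=r,
        s_count=s,
        other_count=other,
        n_distinct_surviving=len(surviving),
        n_reads_input=n_input,
        n_reads_removed=removed,
    )


@dataclass(frozen=True)
class SiteFrequency:
    """Resistant-allele frequency estimate for one site and year."""

    site_id: str
    year: int
    frequency: float
    n_legs: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency must be in [0, 1], got {self.frequency}")


def site_frequency(counts: AlleleCounts) -> SiteFrequency:
    """Resistant reads over all surviving reads for one site."""
    if counts.total == 0:
        raise ValueError(
            f"site {counts.site_id}: no reads survive filtering, "
            "frequency undefined"
        )
    return SiteFrequency(
        site_id=counts.site_id,
        year=counts.year,
        frequency=counts.r_count / counts.total,
        n_legs=counts.n_legs,
    )


def annual_mean_bootstrap(
    site_frequencies: Sequence[SiteFrequency],
    reps: int = 1000,
    seed: Optional[int] = None,
    weight_by_sqrt_legs: bool = False,
) -> tuple[float, Interval]:
    """Annual mean frequency across sites with a percentile bootstrap CI.

    The default is the unweighted across-site mean; optionally each site is
    weighted by the square root of its number of pooled legs (the two are
    nearly identical in practice).  Sites are the resampling unit.
    """
    if not site_frequencies:
        raise ValueError("at least one site frequency is required")
    if weight_by_sqrt_legs:
        import numpy as np

        freqs = np.array([sf.frequency for sf in site_frequencies])
        weights = np.sqrt([sf.n_legs for sf in site_frequencies])
        point = float(np.average(freqs, weights=weights))
        rng = np.random.default_rng(seed)
        n = len(freqs)
        idx = rng.integers(0, n, size=(reps, n))
        means = (freqs[idx] * weights[idx]).sum(axis=1) / weights[idx].sum(axis=1)
        lower, upper = np.quantile(means, [0.025, 0.975])
        return point, Interval(float(lower), float(upper))
    return bootstrap_mean_ci(
        [sf.frequency for sf in site_frequencies], reps=reps, seed=seed
    )


def site_frequency_table(frequencies: Iterable[SiteFrequency]) -> pd.DataFrame:
    """Tidy per-site table (site, year, n_legs, freq) for TSV output."""
    return pd.DataFrame(
        [
            {
                "site": sf.site_id,
                "year": sf.year,
                "n_legs": sf.n_legs,
                "freq": sf.frequency,
            }
            for sf in frequencies
        ]
    )
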
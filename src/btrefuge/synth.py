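"""Synthetic data generators with known ground truth.

Every input the analysis consumes can be generated here: Hardy-Weinberg moth
pools, dual-tagged paired-end amplicon reads (216 bp = 6-bp site tag +
204-bp genomic fragment + reverse-complemented 6-bp site tag, read as 150-bp
pairs), diagnostic-dose bioassay outcomes, and crop-area tables.  Generators
are deterministic under a fixed seed and record the truth they embed (true
allele frequency, variant offset), so recovery can be tested end to end.

Per-base substitution errors are applied at the template (amplicon) level,
before the template is split into the two reads — they model PCR/template
errors that both reads see consistently.  Per-read disagreements would be
rejected at the merge step, so they are not simulated.  Indels, chimeras and
quality-score structure are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicon import (
    INSERT_LENGTH,
    READ_LENGTH,
    TAG_LENGTH,
    SitePool,
    TagScheme,
)
from .refuge import CropRecord
from .stats import BioassayRecord, GenotypeTally

__all__ = [
    "DEFAULT_VARIANT_OFFSET",
    "ReferenceSpec",
    "PoolSpec",
    "BioassaySpec",
    "make_reference",
    "make_tag_scheme",
    "simulate_moth_pool",
    "simulate_pooled_reads",
    "simulate_bioassay",
    "make_crop_table",
    "crop_table_for_refuge_series",
    "write_reference_fasta",
    "read_reference_fasta",
    "write_fastq_pair",
]

#: 0-based position of the biallelic variant within the 204-bp fragment
#: (mid-amplicon; recorded in the reference FASTA header).
DEFAULT_VARIANT_OFFSET = 101

_BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(_BASE_ARR):
    _CODE[_b] = _i


def _rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ReferenceSpec:
    """A synthetic 204-bp reference and where its variant sits."""

    sequence: str
    variant_offset: int
    susceptible_base: str
    resistant_base: str

    def __post_init__(self) -> None:
        if len(self.sequence) != INSERT_LENGTH:
            raise ValueError(f"reference must be {INSERT_LENGTH} nt")
        if self.sequence[self.variant_offset] != self.susceptible_base:
            raise ValueError("reference must carry the susceptible base")

    @property
    def resistant_sequence(self) -> str:
        s = self.sequence
        o = self.variant_offset
        return s[:o] + self.resistant_base + s[o + 1 :]


def make_reference(
    seed: Union[int, np.random.Generator, None] = 0,
    variant_offset: int = DEFAULT_VARIANT_OFFSET,
    susceptible_base: str = "T",
    resistant_base: str = "C",
) -> ReferenceSpec:
    """Draw a random 204-bp fragment carrying the susceptible base."""
    rng = _rng(seed)
    seq = list(rng.choice(list(_BASES), size=INSERT_LENGTH))
    seq[variant_offset] = susceptible_base
    return ReferenceSpec(
        sequence="".join(seq),
        variant_offset=variant_offset,
        susceptible_base=susceptible_base,
        resistant_base=resistant_base,
    )


def make_tag_scheme(
    sites: Sequence[tuple[str, int, int]],
    seed: Union[int, np.random.Generator, None] = 0,
) -> TagScheme:
    """Assign unique random 6-bp dual tags to ``(site_id, n_legs, year)`` specs."""
    rng = _rng(seed)
    pools = []
    used: set[tuple[str, str]] = set()
    for site_id, n_legs, year in sites:
        while True:
            fwd = "".join(rng.choice(list(_BASES), size=TAG_LENGTH))
            rev = "".join(rng.choice(list(_BASES), size=TAG_LENGTH))
            if (fwd, rev) not in used:
                used.add((fwd, rev))
                break
        pools.append(
            SitePool(
                site_id=site_id,
                forward_tag=fwd,
                reverse_tag=rev,
                n_legs=n_legs,
                year=year,
            )
        )
    return TagScheme(pools)


def simulate_moth_pool(
    p: float, n: int, seed: Union[int, np.random.Generator, None] = None
) -> GenotypeTally:
    """Draw ``n`` moth genotypes at Hardy-Weinberg proportions for allele
    frequency ``p`` (multinomial over ss/rs/rr)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    q = 1.0 - p
    ss, rs, rr = rng.multinomial(n, [q * q, 2 * p * q, p * p])
    return GenotypeTally(ss=int(ss), rs=int(rs), rr=int(rr))


@dataclass(frozen=True)
class PoolSpec:
    """How one site's pooled amplicon library is simulated."""

    site_id: str
    year: int
    n_legs: int
    true_p: float
    depth: int
    error_rate: float = 0.001
    seed: Optional[int] = None
    allocation: str = "multinomial"  # or "proportional"

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_p <= 1.0:
            raise ValueError(f"true_p must be in [0, 1], got {self.true_p}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.allocation not in ("multinomial", "proportional"):
            raise ValueError("allocation must be 'multinomial' or 'proportional'")


def _reads_from_template(
    template: str, n_reads: int, error_rate: float, rng: np.random.Generator
) -> list[str]:
    """Replicate a template ``n_reads`` times with iid substitution errors."""
    if n_reads == 0:
        return []
    codes = _CODE[np.frombuffer(template.encode(), dtype=np.uint8)]
    mat = np.tile(codes, (n_reads, 1))
    if error_rate > 0:
        mask = rng.random(mat.shape) < error_rate
        n_err = int(mask.sum())
        if n_err:
            mat[mask] = (mat[mask] + rng.integers(1, 4, size=n_err)) % 4
    out = _BASE_ARR[mat]
    return [row.tobytes().decode() for row in out]


def simulate_pooled_reads(
    tally: GenotypeTally,
    spec: PoolSpec,
    scheme: TagScheme,
    reference: ReferenceSpec,
    read_length: int = READ_LENGTH,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Simulate the paired-end amplicon library for one pooled-leg sample.

    Reads are drawn from the pool's allele copies (two per moth): the number
    of resistant-template reads is binomial in the pool's allele frequency
    under ``allocation='multinomial'``, or the deterministic rounded share
    under ``'proportional'`` (which makes error-free recovery exact whenever
    ``depth`` is a multiple of the number of allele copies).
    """
    if spec.site_id not in scheme.pools:
        raise KeyError(f"site {spec.site_id!r} missing from tag scheme")
    pool = scheme[spec.site_id]
    rng = _rng(spec.seed)
    copies = 2 * tally.total
    if copies == 0:
        raise ValueError("empty genotype tally")
    p_pool = tally.r_copies / copies
    if spec.allocation == "multinomial":
        n_r = int(rng.binomial(spec.depth, p_pool))
    else:
        n_r = int(round(spec.depth * p_pool))
    n_s = spec.depth - n_r

    rev_rc = str(Seq(pool.reverse_tag).reverse_complement())
    templates = (
        (reference.resistant_sequence, n_r),
        (reference.sequence, n_s),
    )
    r1_records: list[SeqRecord] = []
    r2_records: list[SeqRecord] = []
    i = 0
    for insert, n_reads in templates:
        amplicon = pool.forward_tag + insert + rev_rc
        for read in _reads_from_template(amplicon, n_reads, spec.error_rate, rng):
            r1 = read[:read_length]
            r2 = str(Seq(read).reverse_complement())[:read_length]
            rid = f"{spec.site_id}_{spec.year}_{i}"
            qual = [40] * read_length
            r1_records.append(
                SeqRecord(Seq(r1), id=rid, description="", letter_annotations={"phred_quality": qual})
            )
            r2_records.append(
                SeqRecord(Seq(r2), id=rid, description="", letter_annotations={"phred_quality": qual})
            )
            i += 1
    # interleave deterministically so per-site reads are not grouped by allele
    order = rng.permutation(len(r1_records))
    r1_records = [r1_records[j] for j in order]
    r2_records = [r2_records[j] for j in order]
    return r1_records, r2_records


@dataclass(frozen=True)
class BioassaySpec:
    """Hardy-Weinberg population screened at the diagnostic Cry1Ac dose."""

    site_id: str
    year: int
    p: float
    n_larvae: int
    survival_ss: float = 0.0  # susceptibles die at the diagnostic dose
    survival_rs: float = 0.8
    survival_rr: float = 0.9
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("p", "survival_ss", "survival_rs", "survival_rr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_larvae < 1:
            raise ValueError("n_larvae must be >= 1")

    @property
    def expected_survival(self) -> float:
        q = 1.0 - self.p
        return (
            q * q * self.survival_ss
            + 2 * self.p * q * self.survival_rs
            + self.p * self.p * self.survival_rr
        )


def simulate_bioassay(spec: BioassaySpec) -> BioassayRecord:
    """Draw genotypes at Hardy-Weinberg and survival per genotype."""
    rng = _rng(spec.seed)
    tally = simulate_moth_pool(spec.p, spec.n_larvae, rng)
    survivors = sum(
        int(rng.binomial(k, s))
        for k, s in (
            (tally.ss, spec.survival_ss),
            (tally.rs, spec.survival_rs),
            (tally.rr, spec.survival_rr),
        )
    )
    return BioassayRecord(
        site_id=spec.site_id,
        year=spec.year,
        n_tested=spec.n_larvae,
        n_surviving=survivors,
    )


def make_crop_table(
    spec: Mapping[int, Sequence[Mapping[str, object]]]
) -> list[CropRecord]:
    """Build validated crop records from ``{year: [crop dicts]}``.

    Each crop dict needs ``crop, area_ha, bt_fraction, production_weight``.
    """
    if not spec:
        raise ValueError("crop table spec must be non-empty")
    records = []
    for year, crops in sorted(spec.items()):
        if not crops:
            raise ValueError(f"no crops specified for year {year}")
        for crop in crops:
            records.append(
                CropRecord(
                    year=int(year),
                    crop=str(crop["crop"]),
                    area_ha=float(crop["area_ha"]),  # type: ignore[arg-type]
                    bt_fraction=float(crop["bt_fraction"]),  # type: ignore[arg-type]
                    production_weight=float(crop["production_weight"]),  # type: ignore[arg-type]
                )
            )
    return records


def crop_table_for_refuge_series(
    series,
    bt_cotton_area: float = 1.0e6,
    refuge_crop: str = "corn",
    refuge_weight: float = 0.6,
) -> list[CropRecord]:
    """Cotton-plus-one-refuge-crop table whose refuge share matches a series.

    For each year with refuge fraction ``R < 1``, the refuge crop's area is
    chosen so that its production-weighted hectares are ``R/(1-R)`` times the
    Bt cotton area; the resulting table reproduces the series exactly through
    the effective-refuge calculation (a regression round-trip fixture).
    """
    records = []
    for year in series.years():
        r = series[year]
        if not r < 1.0:
            raise ValueError(
                f"year {year}: refuge fraction must be < 1 with Bt cotton present"
            )
        weighted = r / (1.0 - r) * bt_cotton_area
        records.append(
            CropRecord(
                year=year,
                crop="Bt_cotton",
                area_ha=bt_cotton_area,
                bt_fraction=1.0,
                production_weight=1.0,
            )
        )
        records.append(
            CropRecord(
                year=year,
                crop=refuge_crop,
                area_ha=weighted / refuge_weight,
                bt_fraction=0.0,
                production_weight=refuge_weight,
            )
        )
    return records


def write_reference_fasta(ref: ReferenceSpec, path: Union[str, Path]) -> None:
    record = SeqRecord(
        Seq(ref.sequence),
        id="synthetic_amplicon_ref",
        description=(
            f"variant_offset={ref.variant_offset} "
            f"susceptible={ref.susceptible_base} resistant={ref.resistant_base}"
        ),
    )
    SeqIO.write([record], str(path), "fasta")


def read_reference_fasta(path: Union[str, Path]) -> ReferenceSpec:
    record = next(SeqIO.parse(str(path), "fasta"))
    fields = dict(
        part.split("=", 1) for part in record.description.split() if "=" in part
    )
    return ReferenceSpec(
        sequence=str(record.seq),
        variant_offset=int(fields["variant_offset"]),
        susceptible_base=fields["susceptible"],
        resistant_base=fields["resistant"],
    )


def write_fastq_pair(
    r1: Iterable[SeqRecord],
    r2: Iterable[SeqRecord],
    r1_path: Union[str, Path],
    r2_path: Union[str, Path],
) -> None:
    SeqIO.write(list(r1), str(r1_path), "fastq")
    SeqIO.write(list(r2), str(r2_path), "fastq")
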
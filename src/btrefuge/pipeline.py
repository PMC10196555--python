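"""End-to-end orchestration: synthesize -> estimate -> test -> simulate.

``run_full_analysis`` generates a synthetic monitoring dataset whose ground
truth is the effective-refuge scenario trajectory, runs the pooled-amplicon
frequency pipeline and the monitoring statistics on it, simulates the three
refuge scenarios, and writes one TSV per result table plus a parameter-echo
run log.  Everything is deterministic given the config seed, so re-runs are
byte-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import amplicon, popgen, refuge, stats, synth

__all__ = ["RunConfig", "ConfigError", "run_full_analysis", "default_scenarios"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Parameters of one full synthetic-monitoring analysis run."""

    out_dir: Path
    seed: int = 1
    # synthetic monitoring design
    survey_years: tuple[int, ...] = (2010, 2013, 2016, 2019)
    sites_per_year: int = 4
    n_legs: int = 100
    depth: int = 1500
    error_rate: float = 0.001
    bioassay_n: int = 1000
    survival_rs: float = 0.8
    survival_rr: float = 0.9
    # simulation scenario parameters
    start_year: int = 2006
    end_year: int = 2020
    p0: float = popgen.DEFAULT_P0
    h: float = popgen.DEFAULT_H
    cost: float = popgen.DEFAULT_COST
    incomplete_resistance: float = popgen.DEFAULT_INCOMPLETE_RESISTANCE
    w_ss_bt: float = popgen.DEFAULT_W_SS_BT
    cotton_only_refuge: float = 0.10
    bootstrap_reps: int = 1000

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not self.survey_years:
            raise ConfigError("survey_years must be non-empty")
        bad = [
            y
            for y in self.survey_years
            if not self.start_year <= y <= self.end_year
        ]
        if bad:
            raise ConfigError(
                f"survey years {bad} outside simulated span "
                f"[{self.start_year}, {self.end_year}]"
            )

    @classmethod
    def from_yaml(cls, path: Union[str, Path], out_dir=None, seed=None) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if out_dir is not None:
            data["out_dir"] = out_dir
        if seed is not None:
            data["seed"] = seed
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"bad config key: {exc}") from exc


def default_scenarios(config: RunConfig) -> dict[str, popgen.ScenarioConfig]:
    """The three refuge hypotheses as named scenario configs.

    ``no_refuge`` — refuges have no effect (R = 0); ``cotton_only`` — only
    non-Bt cotton acts as refuge (small constant R); ``effective_refuge`` —
    non-Bt cotton plus other non-Bt host plants, with the yearly fraction
    from the fitted northern-China trend.
    """
    years = range(config.start_year, config.end_year + 1)
    shared = dict(
        start_year=config.start_year,
        end_year=config.end_year,
        p0=config.p0,
        h=config.h,
        cost=config.cost,
        incomplete_resistance=config.incomplete_resistance,
        w_ss_bt=config.w_ss_bt,
    )
    return {
        "no_refuge": popgen.ScenarioConfig(
            refuge_series=popgen.RefugeSeries.constant(0.0, years), **shared
        ),
        "cotton_only": popgen.ScenarioConfig(
            refuge_series=popgen.RefugeSeries.constant(
                config.cotton_only_refuge, years
            ),
            **shared,
        ),
        "effective_refuge": popgen.ScenarioConfig(
            refuge_series=refuge.refuge_series_from_regression(years=years),
            **shared,
        ),
    }


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_full_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the whole synthetic analysis; returns the result tables by name."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    seedseq = np.random.SeedSequence(config.seed)

    def child_seed() -> int:
        return int(seedseq.spawn(1)[0].generate_state(1)[0] % (2**31))

    # --- scenarios -------------------------------------------------------
    scenarios = default_scenarios(config)
    trajectories = popgen.run_scenarios(scenarios)
    _write_tsv(trajectories, out / "trajectories.tsv")

    truth = popgen.simulate_trajectory(scenarios["effective_refuge"])

    # --- synthetic monitoring data --------------------------------------
    reference = synth.make_reference(seed=child_seed())
    synth.write_reference_fasta(reference, out / "reference.fasta")
    site_specs = [
        (f"S{i:02d}y{year}", config.n_legs, year)
        for year in config.survey_years
        for i in range(config.sites_per_year)
    ]
    scheme = synth.make_tag_scheme(site_specs, seed=child_seed())
    scheme.to_csv(out / "tag_scheme.csv")

    r1_all, r2_all = [], []
    bioassays = []
    for site_id, n_legs, year in site_specs:
        p_true = truth[year]
        pool_seed = child_seed()
        tally = synth.simulate_moth_pool(p_true, n_legs, seed=pool_seed)
        spec = synth.PoolSpec(
            site_id=site_id,
            year=year,
            n_legs=n_legs,
            true_p=p_true,
            depth=config.depth,
            error_rate=config.error_rate,
            seed=child_seed(),
        )
        r1, r2 = synth.simulate_pooled_reads(tally, spec, scheme, reference)
        r1_all.extend(r1)
        r2_all.extend(r2)
        bioassays.append(
            synth.simulate_bioassay(
                synth.BioassaySpec(
                    site_id=site_id,
                    year=year,
                    p=p_true,
                    n_larvae=config.bioassay_n,
                    survival_rs=config.survival_rs,
                    survival_rr=config.survival_rr,
                    seed=child_seed(),
                )
            )
        )
    synth.write_fastq_pair(
        r1_all, r2_all, out / "reads_R1.fastq", out / "reads_R2.fastq"
    )
    pd.DataFrame(
        [
            {
                "site": b.site_id,
                "year": b.year,
                "n_tested": b.n_tested,
                "n_surviving": b.n_surviving,
            }
            for b in bioassays
        ]
    ).to_csv(out / "bioassays.csv", index=False)

    crops = synth.crop_table_for_refuge_series(
        refuge.refuge_series_from_regression(years=range(2007, 2020))
    )
    refuge.write_crop_table(crops, out / "crops.csv")

    # --- pooled-amplicon frequency estimation ---------------------------
    samples, rejected = amplicon.demultiplex_and_merge(
        out / "reads_R1.fastq", out / "reads_R2.fastq", scheme
    )
    site_freqs = []
    for sample in samples.values():
        counts = amplicon.count_alleles(
            sample,
            reference.sequence,
            reference.variant_offset,
            reference.resistant_base,
            reference.susceptible_base,
        )
        site_freqs.append(amplicon.site_frequency(counts))
    freq_table = amplicon.site_frequency_table(site_freqs).sort_values(
        ["year", "site"]
    )
    _write_tsv(freq_table, out / "site_frequencies.tsv")

    annual_rows = []
    for year in config.survey_years:
        year_freqs = [sf for sf in site_freqs if sf.year == year]
        mean, ci = amplicon.annual_mean_bootstrap(
            year_freqs, reps=config.bootstrap_reps, seed=child_seed()
        )
        annual_rows.append(
            {
                "year": year,
                "n_sites": len(year_freqs),
                "mean_freq": mean,
                "ci_lower": ci.lower,
                "ci_upper": ci.upper,
                "true_freq": truth[year],
            }
        )
    annual = pd.DataFrame(annual_rows)
    _write_tsv(annual, out / "annual_frequency.tsv")

    # --- bioassay summary and cross-method statistics --------------------
    bio_rows = []
    for year in config.survey_years:
        year_records = [b for b in bioassays if b.year == year]
        mean_pct, ci = stats.resistance_percentage(
            year_records, reps=config.bootstrap_reps, seed=child_seed()
        )
        bio_rows.append(
            {
                "year": year,
                "n_sites": len(year_records),
                "resistant_pct": mean_pct,
                "ci_lower": ci.lower,
                "ci_upper": ci.upper,
            }
        )
    bio_summary = pd.DataFrame(bio_rows)
    _write_tsv(bio_summary, out / "bioassay_summary.tsv")

    # trend and cross-method statistics need at least 3 surveyed years
    trend = corr = None
    if len(annual) >= 3:
        trend = stats.log_linear_regression(annual["year"], annual["mean_freq"])
        corr = stats.log_pearson_correlation(
            bio_summary["resistant_pct"], annual["mean_freq"]
        )

    # the refuge trend is linear on the natural scale, refit accordingly
    from scipy.stats import linregress

    refuge_series = refuge.effective_refuge_by_year(crops)
    lin = linregress(refuge_series.index.values, refuge_series.values)
    refuge_frame = refuge_series.rename_axis("year").reset_index()
    _write_tsv(refuge_frame, out / "effective_refuge.tsv")

    stat_rows = [
        {
            "statistic": "refuge_trend_slope_pct_per_year",
            "value": lin.slope,
            "detail": f"R2={lin.rvalue**2:.4f}",
        }
    ]
    if trend is not None:
        stat_rows.insert(
            0,
            {
                "statistic": "log10_freq_trend_slope",
                "value": trend.slope,
                "detail": f"R2={trend.r_squared:.4f} p={trend.p_value:.4g} df={trend.df}",
            },
        )
        stat_rows.insert(
            1,
            {
                "statistic": "log10_bioassay_vs_freq_r",
                "value": corr.r,
                "detail": f"p={corr.p_value:.4g} df={corr.df}",
            },
        )
    stats_frame = pd.DataFrame(stat_rows)
    _write_tsv(stats_frame, out / "statistics.tsv")

    # --- predicted-vs-observed comparison -------------------------------
    wide = trajectories.pivot(index="year", columns="scenario", values="p")
    comparison = wide.reset_index().merge(
        annual[["year", "mean_freq", "ci_lower", "ci_upper"]],
        on="year",
        how="left",
    )
    comparison = comparison.rename(columns={"mean_freq": "observed_synthetic"})
    _write_tsv(comparison, out / "comparison.tsv")

    with open(out / "run.log", "w") as fh:
        fh.write("btrefuge full analysis run\n")
        for key, value in asdict(config).items():
            fh.write(f"param {key} = {value}\n")
        fh.write(f"result rejected_read_pairs = {rejected}\n")
        fh.write(f"result n_sites = {len(site_freqs)}\n")
        for row in annual_rows:
            fh.write(
                "result year={year} mean_freq={mean_freq:.6f} "
                "ci=[{ci_lower:.6f},{ci_upper:.6f}] truth={true_freq:.6f}\n".format(
                    **row
                )
            )

    return {
        "trajectories": trajectories,
        "site_frequencies": freq_table,
        "annual_frequency": annual,
        "bioassay_summary": bio_summary,
        "statistics": stats_frame,
        "effective_refuge": refuge_frame,
        "comparison": comparison,
    }
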
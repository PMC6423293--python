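"""Effective population size and end-to-end orchestration.

For a diploid, the population mutation parameter is theta = 4 * Ne * mu and
is estimated by neutral nucleotide diversity, so Ne = pi_s / (4 * mu). The
full-analysis driver chains simulation, filtering, rate and false-negative
estimation, diversity/LD summaries and the Ne calculation into one
reproducible JSON-able report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import __version__ as _version
from .datasets import CODING_SIZE_BP, DUCKWEED_PI_S
from .false_negative import spikein_fn
from .filtering import PipelineConfig, run_ma_pipeline
from .popgen import (
    GenotypeMatrix,
    fit_sved,
    hudson_fst,
    ld_distance_at,
    pairwise_differences,
    segregating_sites,
    tajimas_d,
)
from .rates import (
    MALineMeta,
    TreatmentRate,
    coding_expectation,
    mutation_spectrum,
    treatment_rate,
    lines_from_pipeline,
)
from .synthetic import (
    ANCESTOR_ID,
    SimConfig,
    simulate_coalescent,
    simulate_ma_experiment,
    spike_in,
)


def round_sig(x: float, sig: int = 2) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass
class NeEstimate:
    """Ne = pi_s / (4 mu); theta is the implied population mutation
    parameter (equal to pi_s under neutrality)."""

    pi_s: float
    mu: float
    ne: float
    theta: float
    ne_2sf: float

    def display(self) -> str:
        return f"Ne = {self.ne_2sf:.2g} (pi_s = {self.pi_s}, mu = {self.mu:.3g})"


def effective_size(pi_s: float, mu: float) -> NeEstimate:
    if pi_s <= 0 or mu <= 0:
        raise ValueError("pi_s and mu must be positive")
    ne = pi_s / (4.0 * mu)
    return NeEstimate(pi_s=pi_s, mu=mu, ne=ne, theta=pi_s, ne_2sf=round_sig(ne, 2))


@dataclass
class FullAnalysisConfig:
    """Inputs for the end-to-end run.

    When ``table_lines`` is supplied, rate estimation uses those printed
    per-line summaries directly; otherwise lines are derived from the
    synthetic MA experiment. The LD stage fits Sved's curve to a decay
    series generated at a known beta (the simulator has no recombination,
    so LD structure cannot come from the coalescent sample itself).
    """

    sim: SimConfig = field(default_factory=SimConfig)
    run_simulation: bool = True
    table_lines: list[MALineMeta] | None = None
    spike_n: int = 1000
    spike_freq_mean: float = 0.5
    spike_freq_sd: float = 0.1
    coalescent_n: int = 20
    coalescent_theta: float = 1.0
    run_popgen: bool = True
    ld_beta: float = 1e-4
    ld_n: int = 20
    ld_noise_sd: float = 0.01
    ld_r2_target: float = 0.33
    coding_size: float = CODING_SIZE_BP
    ne_pi_s: float = DUCKWEED_PI_S
    ne_treatment: str = "outdoor-UV"
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 0


def _rate_section(lines: list[MALineMeta], coding_size: float) -> dict:
    by_treatment: dict[str, list[MALineMeta]] = {}
    for m in lines:
        by_treatment.setdefault(m.treatment, []).append(m)
    section: dict[str, dict] = {}
    for t in sorted(by_treatment):
        tr = treatment_rate(by_treatment[t])
        ce = coding_expectation(tr, coding_size)
        section[t] = {
            "mean": tr.mean, "ci_low": tr.ci_low, "ci_high": tr.ci_high,
            "total_k": tr.total_k, "display": tr.display(),
            "coding_expectation_mean": ce.mean, "coding_expectation_sd": ce.sd,
        }
    return section


def run_full_analysis(config: FullAnalysisConfig) -> dict:
    """Execute every stage the configuration enables; identical config and
    seed reproduce the report exactly."""
    report: dict = {"provenance": {
        "package": "malines", "version": _version, "seed": config.seed,
        "thresholds": asdict(config.pipeline),
    }}

    treatment_rates: dict[str, TreatmentRate] = {}

    if config.run_simulation:
        sim_cfg = config.sim
        calls, depths, truth = simulate_ma_experiment(sim_cfg)
        result = run_ma_pipeline(calls, depths, config.pipeline)
        spectrum, titv = mutation_spectrum(result.point_candidates)
        sim_lines = lines_from_pipeline(
            result,
            lambda s: None if s == ANCESTOR_ID else sim_cfg.treatment_of(s),
            generations=sim_cfg.generations,
        )
        n_true = sum(len(v) for v in truth.true_mutations.values())
        report["simulation"] = {
            "filter_report": result.report,
            "n_true_mutations": n_true,
            "n_detected_point": len(result.point_candidates),
            "spectrum": dict(spectrum), "titv": titv,
            "rates": _rate_section(sim_lines, config.coding_size),
        }
        # spike-in false-negative stage on the simulated experiment
        if config.spike_n > 0:
            offspring_masks = {s: m for s, m in result.masks.items()
                               if s != config.pipeline.ancestor}
            spiked_calls, spike_truth = spike_in(
                calls, offspring_masks, config.spike_n,
                config.spike_freq_mean, config.spike_freq_sd,
                seed=config.seed, depth_profiles=depths,
            )
            spiked_result = run_ma_pipeline(spiked_calls, depths, config.pipeline)
            fn = spikein_fn(spike_truth, spiked_result.point_candidates)
            report["fn"] = {
                "method": fn.method, "rate": fn.rate,
                "ci_low": fn.ci_low, "ci_high": fn.ci_high,
                "n_trials": fn.n_trials, "n_missed": fn.n_missed,
                "display": fn.display(),
            }

    if config.table_lines is not None:
        report["rates"] = _rate_section(config.table_lines, config.coding_size)
        for t in {m.treatment for m in config.table_lines}:
            treatment_rates[t] = treatment_rate(
                [m for m in config.table_lines if m.treatment == t]
            )

    if config.run_popgen:
        rng = np.random.default_rng([config.seed, 31])
        sample = simulate_coalescent(config.coalescent_n, config.coalescent_theta,
                                     rng=rng)
        m = GenotypeMatrix.from_haplotypes(sample.haplotypes,
                                           callable_length=1)
        S = segregating_sites(m)
        diversity = {
            "pi_per_locus": pairwise_differences(m),
            "segregating_sites": S,
            "n_haplotypes": config.coalescent_n,
            "theta": config.coalescent_theta,
        }
        if S > 0:
            diversity["tajimas_d"] = tajimas_d(S, config.coalescent_n,
                                               pairwise_differences(m))
        # exchangeable-halves F_st: expected ~0 under panmixia
        half = config.coalescent_n // 2
        if half >= 2 and S > 0:
            a = GenotypeMatrix.from_haplotypes(sample.haplotypes[:half],
                                               callable_length=1)
            b = GenotypeMatrix.from_haplotypes(sample.haplotypes[half:],
                                               callable_length=1)
            try:
                diversity["fst_exchangeable_halves"] = hudson_fst(a, b)
            except ValueError:
                pass
        report["diversity"] = diversity

        # Sved-decay round trip at a known beta
        d = np.arange(50.0, 10_000.0, 100.0)
        y = 1.0 / (1.0 + 4.0 * config.ld_beta * d) + 1.0 / config.ld_n
        y = y + rng.normal(0.0, config.ld_noise_sd, size=d.size)
        bins = [(float(di), float(yi), 100) for di, yi in zip(d, y)]
        fit = fit_sved(bins, config.ld_n)
        report["ld"] = {
            "true_beta": config.ld_beta, "fitted_beta": fit.beta,
            "n": config.ld_n, "rss": fit.rss,
            "useful_ld_distance_bp": ld_distance_at(fit, config.ld_r2_target),
            "r2_target": config.ld_r2_target,
        }

    mu_source = treatment_rates.get(config.ne_treatment)
    if mu_source is not None and mu_source.mean > 0:
        est = effective_size(config.ne_pi_s, mu_source.mean)
        report["ne"] = {
            "pi_s": est.pi_s, "mu": est.mu, "mu_treatment": config.ne_treatment,
            "ne": est.ne, "ne_2sf": est.ne_2sf, "theta": est.theta,
            "caveat": "assumes equal mutation rates in clonal and sexual "
                      "phases and populations at genetic equilibrium",
        }
    else:
        report["ne"] = {"absent": True,
                        "reason": "no positive rate for the configured treatment"}
    return report
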
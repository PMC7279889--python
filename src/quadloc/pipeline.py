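"""End-to-end pipeline: simulation config -> full enrichment report.

Chains the stages the analysis performs on real data — localization-ratio
quantification and target calling, G-quadruplex scanning, feature
enrichment, Bind-n-Seq quantification — over the synthetic generators, and
reports recovery-vs-truth confusion counts next to the headline enrichment
statistics. Every stage's outputs are written to the run directory and the
report JSON is byte-deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np

from . import enrichment, gquad, localization, rbns, synthio
from .io import write_bed, write_fasta, write_tsv

logger = logging.getLogger("quadloc")

__all__ = ["RunConfig", "run_all", "round_floats", "dump_report"]


@dataclass(frozen=True)
class RunConfig:
    """All stage parameters plus the global seed and output directory."""

    # simulation
    n_genes: int = 2000
    n_replicates: int = 3
    target_fraction: float = 0.025
    delta_lr_effect: float = -1.0
    nb_dispersion: float = 0.1
    mean_depth: float = 500.0
    g4_prob_target: float = 1.0
    g4_prob_nontarget: float = 0.0
    # localization
    min_count: int = 10
    pseudocount: float = 0.5
    fdr_max: float = 0.1
    lfc_min: float = 0.25
    test_method: str = "moderated"
    # G4 scanning
    linker_max: int = 6
    window: int = 80
    step: int = 20
    ratio_min: float = 5.0
    upstream: int = 60
    # enrichment
    k: int = 6
    alpha: float = 0.05
    # rbns
    rbns_n_reads: int = 50_000
    rbns_read_len: int = 40
    rbns_enrichment: float = 10.0
    rbns_g4_fraction: float = 0.1
    n_subsamples: int = 20
    subsample_fraction: float = 0.2
    # rt stops
    rt_depth: int = 1000
    rt_stop_rate_g4: float = 0.05
    rt_stop_rate_bg: float = 0.001
    # global
    seed: int = 0
    outdir: str = "quadloc_run"
    plots: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d["outdir"] = str(d.get("outdir", cls.outdir))
        return cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()})

    def simulation_config(self) -> synthio.SimulationConfig:
        return synthio.SimulationConfig(
            n_genes=self.n_genes,
            n_replicates=self.n_replicates,
            target_fraction=self.target_fraction,
            delta_lr_effect=self.delta_lr_effect,
            nb_dispersion=self.nb_dispersion,
            mean_depth=self.mean_depth,
            g4_prob_target=self.g4_prob_target,
            g4_prob_nontarget=self.g4_prob_nontarget,
            rbns_enrichment=self.rbns_enrichment,
            seed=self.seed,
        )


def round_floats(obj: Any, sig: int = 6) -> Any:
    """Recursively round floats to ``sig`` significant digits for stable JSON."""
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        if obj != 0 and abs(obj) < 1e-300:
            obj = float(np.copysign(1e-300, obj))
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, (np.floating,)):
        return round_floats(float(obj), sig)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, dict):
        return {str(k): round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v, sig) for v in obj]
    return obj


def dump_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(round_floats(report), fh, sort_keys=True, indent=2)
        fh.write("\n")


def _confusion(called: set[str], truth_targets: set[str], universe: set[str]) -> dict:
    tp = len(called & truth_targets)
    fp = len(called - truth_targets)
    fn = len(truth_targets - called)
    tn = len(universe) - tp - fp - fn
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "recall": tp / len(truth_targets) if truth_targets else float("nan"),
        "empirical_fdr": fp / max(tp + fp, 1),
    }


def run_all(config: RunConfig) -> dict:
    """Run simulate -> localize -> classify -> scan -> enrich -> rbns.

    Writes stage outputs under ``config.outdir`` and returns the report
    dict (also written as report.json).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "config"
    report: dict[str, Any] = {"seed": config.seed}
    try:
        (out / "config.json").write_text(config.to_json() + "\n")

        stage = "simulate"
        sim = config.simulation_config()
        utr3, truth = synthio.make_transcriptome(sim)
        counts, meta = synthio.simulate_counts(truth, sim)
        write_fasta(utr3, out / "utr3.fa")
        (out / "truth.json").write_text(truth.to_json() + "\n")
        write_tsv(counts, out / "counts.tsv")
        write_tsv(meta, out / "meta.tsv", index=False)
        logger.info("simulated %d genes, %d samples", *counts.shape)

        stage = "localize"
        filtered = localization.filter_low_counts(counts, config.min_count)
        lrtab = localization.compute_lr(
            filtered, meta, pseudocount=config.pseudocount
        )
        cond1, cond2 = sim.conditions
        results = localization.diff_localization(
            lrtab, cond1, cond2, method=config.test_method
        )
        results = localization.classify_targets_fdr(
            results, fdr_max=config.fdr_max, direction="decrease"
        )
        excluded = counts.index.difference(filtered.index)
        write_tsv(results, out / "localization_results.tsv")
        called = set(results.index[results["class"] == "target"])
        tested_targets = set(truth.target_ids) & set(filtered.index)
        report["localization"] = {
            "n_genes": int(len(counts)),
            "n_tested": int(len(filtered)),
            "n_excluded_low_count": int(len(excluded)),
            "n_called_targets": len(called),
            "confusion_vs_truth": _confusion(
                called, tested_targets, set(filtered.index)
            ),
        }
        logger.info("called %d localization targets", len(called))

        stage = "scan-g4"
        matches = {
            g: gquad.scan_wgga(gquad.RnaSequence(g, s), config.linker_max)
            for g, s in utr3.items()
        }
        write_bed([m for ms in matches.values() for m in ms], out / "wgga.bed")
        density = {g: len(ms) / len(utr3[g]) for g, ms in matches.items()}

        stage = "rt-stops"
        rt = synthio.simulate_rt_stops(
            truth,
            stop_rate_g4=config.rt_stop_rate_g4,
            stop_rate_bg=config.rt_stop_rate_bg,
            depth=config.rt_depth,
        )
        calls = gquad.call_rt_stop_g4(rt, config.ratio_min, config.upstream)
        planted = {
            g: {e for _, e in ivs} for g, ivs in truth.g4_intervals.items()
        }
        recovered = {
            c.transcript_id
            for c in calls
            if c.stop_position in planted.get(c.transcript_id, set())
        }
        report["rt_stop"] = {
            "n_planted_g4_genes": len(planted),
            "n_calls": len(calls),
            "recovery": len(recovered) / len(planted) if planted else float("nan"),
        }

        stage = "enrich"
        tested = results.index
        tgt_called = [g for g in tested if g in called]
        ntg_called = [g for g in tested if g not in called]
        kmer_df = enrichment.kmer_enrichment(
            [utr3[g] for g in tgt_called],
            [utr3[g] for g in ntg_called],
            k=config.k,
            alpha=config.alpha,
        )
        write_tsv(kmer_df, out / "kmer_enrichment.tsv", index=False)
        top = kmer_df.loc[kmer_df["significant"]].head(10)
        dens_t = np.array([density[g] for g in tgt_called])
        dens_n = np.array([density[g] for g in ntg_called])
        eff = enrichment.effect_size("utr3_wgga_density", dens_t, dens_n)
        report["enrichment"] = {
            "n_significant_kmers": int(kmer_df["significant"].sum()),
            "top_kmers": top["kmer"].tolist(),
            "top_kmers_gga_fraction": (
                float(np.mean(["GGA" in k for k in top["kmer"]]))
                if len(top)
                else float("nan")
            ),
            "wgga_density_cliffs_delta": eff.cliffs_delta,
            "wgga_density_wilcoxon_p": eff.p,
        }

        stage = "rbns"
        report["rbns"] = {}
        for condition in ("K", "Li"):
            pool_in, pool_bnd = synthio.simulate_rbns(
                read_len=config.rbns_read_len,
                n_reads=config.rbns_n_reads,
                enrichment=config.rbns_enrichment,
                condition=condition,
                g4_fraction=config.rbns_g4_fraction,
                seed=config.seed,
            )
            boot = rbns.bootstrap_enrichment(
                pool_in,
                pool_bnd,
                rbns.wgga_matcher(config.linker_max),
                n_subsamples=config.n_subsamples,
                subsample_fraction=config.subsample_fraction,
                seed=config.seed,
                motif_class="wgga_regex",
            )
            report["rbns"][condition] = {
                "fraction_input": boot.fraction_input,
                "fraction_bound": boot.fraction_bound,
                "ratio": boot.ratio,
                "bootstrap_mean": boot.bootstrap_mean,
                "bootstrap_sd": boot.bootstrap_sd,
                "expected_ratio": synthio.expected_fraction_ratio(
                    boot.fraction_input,
                    config.rbns_enrichment if condition == "K" else 1.0,
                ),
            }

        if config.plots:
            stage = "plots"
            _write_plots(results, dens_t, dens_n, out)
    except Exception as exc:  # pragma: no cover - abort path
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    dump_report(report, out / "report.json")
    return report


def _write_plots(results, dens_t, dens_n, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(
        results["delta_lr"],
        -np.log10(np.clip(results["p"], 1e-300, 1)),
        s=4,
        c=np.where(results["class"] == "target", "crimson", "gray"),
    )
    ax.set_xlabel("delta LR (log2)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(out / "volcano.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.boxplot([dens_t, dens_n], tick_labels=["targets", "nontargets"])
    ax.set_ylabel("WGGA matches / nt (3'UTR)")
    fig.tight_layout()
    fig.savefig(out / "density.png", dpi=120)
    plt.close(fig)
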
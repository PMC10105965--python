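"""Shared group-comparison statistics, exclusion bookkeeping, and the
end-to-end pipeline orchestrator.

All tests are two-tailed at α = 0.05; p > 0.05 is flagged 'n.s'.  No
multiple-testing correction is applied; the report records how many tests
were run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["ComparisonSpec", "AnalysisReport", "run_comparison", "run_pipeline", "demo_config"]

ALPHA = 0.05

TESTS = ("unpaired_t", "paired_t", "two_way_anova", "ks_two_sample", "pearson")


@dataclass
class ComparisonSpec:
    test: str
    alpha: float = ALPHA
    tails: int = 2
    grouping: str = "genotype"
    unit: str = "animal"  # {animal, cell, bout}
    name: str = ""

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise ValueError(f"unknown test {self.test!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tails != 2:
            raise ValueError("only two-tailed tests are supported")


@dataclass
class AnalysisReport:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    comparisons: list[dict] = field(default_factory=list)
    exclusions: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: int = 0

    def exclude(self, unit: str, reason: str) -> None:
        if not reason:
            raise ValueError("every exclusion needs a reason")
        self.exclusions.append({"unit": unit, "reason": reason})

    @property
    def n_tests(self) -> int:
        return len(self.comparisons)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in sorted(self.tables):
            self.tables[name].to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
        pd.DataFrame(self.comparisons).to_csv(
            out / "comparisons.csv", index=False, float_format="%.10g"
        )
        pd.DataFrame(self.exclusions, columns=["unit", "reason"]).to_csv(
            out / "exclusions.csv", index=False
        )
        snapshot = {"seed": self.seed, "config": self.config, "n_tests": self.n_tests}
        (out / "config_snapshot.json").write_text(
            json.dumps(snapshot, indent=2, sort_keys=True, default=str)
        )


def _sig_flag(p: float | None, alpha: float) -> str:
    if p is None:
        return "undefined"
    return "n.s" if p > alpha else "significant"


def run_comparison(data: dict, spec: ComparisonSpec) -> dict:
    """Run the named two-tailed test and return a report row.

    ``data`` carries test-specific keys: unpaired_t/ks_two_sample expect
    {'a', 'b'}; paired_t and pearson expect {'x', 'y'}; two_way_anova
    expects a long-format DataFrame under 'frame' with columns
    (group, level, value).  Degenerate inputs are reported, not raised.
    """
    row: dict = {
        "name": spec.name or spec.test,
        "test": spec.test,
        "unit": spec.unit,
        "statistic": None,
        "df": None,
        "p": None,
        "n": None,
    }
    if spec.test == "unpaired_t":
        a = np.asarray(data["a"], float)
        b = np.asarray(data["b"], float)
        row["n"] = f"{len(a)},{len(b)}"
        if len(a) < 2 or len(b) < 2:
            row["error"] = "insufficient n"
        elif np.var(a) == 0 and np.var(b) == 0:
            if np.mean(a) == np.mean(b):
                row.update(statistic=0.0, p=1.0, df=len(a) + len(b) - 2)
            else:
                row["error"] = "zero variance in both groups"
        else:
            t, p = stats.ttest_ind(a, b)
            row.update(statistic=float(t), p=float(p), df=len(a) + len(b) - 2)
    elif spec.test == "paired_t":
        x = np.asarray(data["x"], float)
        y = np.asarray(data["y"], float)
        row["n"] = len(x)
        if len(x) != len(y):
            raise ValueError("paired test requires equal lengths")
        diff = x - y
        if len(x) < 2:
            row["error"] = "insufficient n"
        elif np.var(diff) == 0:
            if np.all(diff == 0):
                row.update(statistic=0.0, p=1.0, df=len(x) - 1)
            else:
                row["error"] = "zero variance of paired differences"
        else:
            t, p = stats.ttest_rel(x, y)
            row.update(statistic=float(t), p=float(p), df=len(x) - 1)
    elif spec.test == "ks_two_sample":
        a = np.asarray(data["a"], float)
        b = np.asarray(data["b"], float)
        row["n"] = f"{len(a)},{len(b)}"
        if len(a) == 0 or len(b) == 0:
            row["error"] = "empty sample"
        else:
            d, p = stats.ks_2samp(a, b)
            row.update(statistic=float(d), p=float(p))
    elif spec.test == "pearson":
        x = np.asarray(data["x"], float)
        y = np.asarray(data["y"], float)
        row["n"] = len(x)
        if len(x) < 3:
            row["error"] = "insufficient n"
        elif np.var(x) == 0 or np.var(y) == 0:
            row["error"] = "zero variance"
        else:
            r, p = stats.pearsonr(x, y)
            row.update(statistic=float(r), p=float(p), df=len(x) - 2)
    elif spec.test == "two_way_anova":
        from septodg.ephys import fi_group_compare  # shares the ANOVA path

        frame: pd.DataFrame = data["frame"]
        tables = {
            g: [
                sub.rename(columns={"level": "current_pa", "value": "spike_count"})[
                    ["current_pa", "spike_count"]
                ]
                for _, sub in gdf.groupby("cell")
            ]
            for g, gdf in frame.groupby("group")
        }
        res = fi_group_compare(tables)
        row.update(statistic=res["genotype_F"], p=res["genotype_p"])
        row["interaction_p"] = res["interaction_p"]
        row["n"] = int(frame.groupby(["group", "cell"]).ngroups)
    row["flag"] = _sig_flag(row["p"], spec.alpha)
    return row


# ---------------------------------------------------------------------------
# pipeline


def demo_config() -> dict:
    """Small all-synthetic configuration that exercises every stage."""
    return {
        "photometry": {
            "n_wt": 5,
            "n_ad": 4,
            "duration_s": 300.0,
            "wt_rate_per_min": 4.0,
            "ad_rate_per_min": 8.0,
            "noise_sd": 0.3,
            "motion_correct": True,
        },
        "perievent": {"n_bouts": 30, "rho_familiarization": 0.8, "rho_test": 0.0},
        "behavior": {"n_per_group": 4, "duration_s": 120.0},
        "ephys": {
            "n_cells": 5,
            "duration_s": 60.0,
            "sipsc_rate_hz": 4.0,
            "opto_rate_modulation": 0.5,
        },
        "tracing": {"process_count": 20, "soma_count": 60},
    }


def run_pipeline(
    config: dict | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    make_figures: bool = False,
) -> AnalysisReport:
    """Execute simulate → analyze → compare across all stages.

    Deterministic given (config, seed).  Each stage raises with a
    stage-attributed error on failure; completed tables are preserved on the
    report object.
    """
    from septodg import behavior, ephys, perievent, photometry, tracing
    from septodg import synthetic_data as synth

    cfg = demo_config()
    if config:
        for k, v in config.items():
            if isinstance(v, dict) and k in cfg:
                cfg[k].update(v)
            else:
                cfg[k] = v
    report = AnalysisReport(config=cfg, seed=seed)

    stage = "photometry"
    try:
        pc = cfg["photometry"]
        rows = []
        groups: dict[str, list[float]] = {"WT": [], "AD": []}
        for genotype, n_animals, rate in (
            ("WT", pc["n_wt"], pc["wt_rate_per_min"]),
            ("AD", pc["n_ad"], pc["ad_rate_per_min"]),
        ):
            for a in range(n_animals):
                sim = synth.SimConfig(
                    seed=seed,
                    genotype_params={
                        genotype: synth.GenotypeParams(event_rate_per_min=rate)
                    },
                    photometry=synth.PhotometryParams(
                        duration_s=pc["duration_s"], noise_sd=pc["noise_sd"]
                    ),
                )
                session, _truth = synth.simulate_photometry_session(
                    sim, genotype=genotype, site="DG", animal_id=f"{genotype}{a}"
                )
                dff_g = photometry.compute_dff(session.f_gcamp, session.time)
                if pc["motion_correct"]:
                    dff_m = photometry.compute_dff(session.f_mcherry, session.time)
                    dff_g = photometry.motion_correct(dff_g, dff_m)
                events = photometry.detect_events(dff_g)
                summary = photometry.session_activity(events)
                summary.update(animal_id=session.animal_id, genotype=genotype, site="DG")
                rows.append(summary)
                groups[genotype].append(summary["event_rate_per_min"])
        report.tables["photometry_summary"] = pd.DataFrame(rows)[
            ["animal_id", "genotype", "site", "event_count", "event_rate_per_min",
             "auc", "suprathreshold_fraction"]
        ]
        report.comparisons.append(
            run_comparison(
                {"a": groups["WT"], "b": groups["AD"]},
                ComparisonSpec(test="unpaired_t", unit="animal", name="dg_event_rate_wt_vs_ad"),
            )
        )

        stage = "perievent"
        pe = cfg["perievent"]
        coupling_rows = []
        for phase, rho in (
            ("familiarization", pe["rho_familiarization"]),
            ("test", pe["rho_test"]),
        ):
            sim = synth.SimConfig(
                seed=seed + (0 if phase == "familiarization" else 1),
                photometry=synth.PhotometryParams(duration_s=pc["duration_s"], noise_sd=0.05),
            )
            bouts = synth.default_bout_script(pc["duration_s"], n_bouts=pe["n_bouts"])
            dg, ms, truth = synth.simulate_paired_sessions(sim, bouts=bouts, rho=rho)
            dff_dg = photometry.compute_dff(dg.f_gcamp, dg.time)
            dff_ms = photometry.compute_dff(ms.f_gcamp, ms.time)
            mat_dg = perievent.build_perievent(dff_dg, truth.bouts)
            mat_ms = perievent.build_perievent(dff_ms, truth.bouts)
            resp_dg = perievent.bout_responses(mat_dg)
            resp_ms = perievent.bout_responses(mat_ms)
            res = perievent.coupling(resp_dg, resp_ms)
            coupling_rows.append(
                {"phase": phase, "true_rho": rho, "r": res.r, "p": res.p, "n_bouts": res.n}
            )
            report.comparisons.append(
                run_comparison(
                    {"x": resp_dg, "y": resp_ms},
                    ComparisonSpec(test="pearson", unit="bout", name=f"ms_dg_coupling_{phase}"),
                )
            )
        report.tables["coupling"] = pd.DataFrame(coupling_rows)

        stage = "behavior"
        bc = cfg["behavior"]
        score_rows = []
        scores: dict[str, list[float]] = {"WT": [], "AD": []}
        for genotype in ("WT", "AD"):
            for a in range(bc["n_per_group"]):
                n_bouts = 12 if genotype == "WT" else 8
                sim = synth.SimConfig(seed=seed * 1000 + a * 2 + (genotype == "AD"))
                script = synth.default_bout_script(
                    bc["duration_s"], n_bouts=n_bouts, bout_s=1.0 if genotype == "WT" else 0.8
                )
                track, truth = synth.simulate_behavior_track(
                    sim, phase="test", scripted_bouts=script, duration_s=bc["duration_s"]
                )
                bouts = behavior.detect_bouts(track)
                score = behavior.recognition_score(bouts, novel_object="B")
                if score.excluded:
                    report.exclude(f"{genotype}{a}", score.exclusion_reason)
                    continue
                score_rows.append(
                    {"animal_id": f"{genotype}{a}", "genotype": genotype,
                     "t_novel": score.t_novel, "t_familiar": score.t_familiar,
                     "score": score.score, "latency_s": score.latency_to_first_bout}
                )
                scores[genotype].append(score.score)
        report.tables["behavior_scores"] = pd.DataFrame(score_rows)
        if all(len(v) >= 2 for v in scores.values()):
            report.comparisons.append(
                run_comparison(
                    {"a": scores["WT"], "b": scores["AD"]},
                    ComparisonSpec(test="unpaired_t", unit="animal", name="recognition_score"),
                )
            )

        stage = "ephys"
        ec = cfg["ephys"]
        opto_cells = []
        amp_tables: dict[str, list] = {"WT": [], "AD": []}
        for genotype, mu in (("WT", np.log(45.0)), ("AD", np.log(55.0))):
            for c in range(ec["n_cells"]):
                sim = synth.SimConfig(
                    seed=seed * 7919 + c * 2 + (genotype == "AD"),
                    ephys=synth.EphysParams(
                        duration_s=ec["duration_s"],
                        sipsc_rate_hz=ec["sipsc_rate_hz"],
                        amp_lognorm_mu=mu,
                        opto_rate_modulation=ec["opto_rate_modulation"],
                    ),
                )
                epochs = synth.default_light_epochs(ec["duration_s"])
                sweeps, _truth = synth.simulate_sipsc_trace(
                    sim, light_epochs=epochs, cell_id=f"{genotype}{c}"
                )
                qc = ephys.qc_access_resistance(sweeps)
                if qc["status"] == "fail":
                    report.exclude(sweeps.cell_id, "access resistance drift > 20%")
                    continue
                table = ephys.detect_sipscs(sweeps.sweeps[0])
                amp_tables[genotype].append(table)
                if genotype == "AD":
                    opto_cells.append((table, epochs))
        group_stats = ephys.sipsc_group_stats(amp_tables)
        report.tables["sipsc_groups"] = pd.DataFrame(
            [
                {"genotype": g, **group_stats["per_group"][g]}
                for g in group_stats["groups"]
            ]
        )
        report.comparisons.append(
            {
                "name": "sipsc_amplitude_ks",
                "test": "ks_two_sample",
                "unit": "event",
                "statistic": group_stats["amplitude_ks"]["D"],
                "df": None,
                "p": group_stats["amplitude_ks"]["p"],
                "n": None,
                "flag": _sig_flag(group_stats["amplitude_ks"]["p"], ALPHA),
            }
        )
        opto = ephys.opto_epoch_compare(opto_cells)
        ft = opto["frequency_paired_t"]
        report.comparisons.append(
            {
                "name": "opto_frequency_pre_vs_light",
                "test": "paired_t",
                "unit": "cell",
                "statistic": ft.get("t"),
                "df": None,
                "p": ft.get("p"),
                "n": opto["n_cells"],
                "flag": _sig_flag(ft.get("p"), ALPHA),
            }
        )

        # intrinsic properties + F-I on a pair of simulated cells per group
        fi_tables: dict[str, list] = {"WT": [], "AD": []}
        intrinsic_rows = []
        for genotype, r_mohm in (("WT", 150.0), ("AD", 110.0)):
            for c in range(3):
                sim = synth.SimConfig(
                    seed=seed * 104729 + c * 2 + (genotype == "AD"),
                    ephys=synth.EphysParams(r_mohm=r_mohm),
                )
                sweeps, _truth = synth.simulate_current_steps(sim, cell_id=f"{genotype}{c}")
                props = ephys.intrinsic_properties(sweeps)
                fi_tables[genotype].append(props.fi_table)
                intrinsic_rows.append(
                    {"cell_id": f"{genotype}{c}", "genotype": genotype,
                     "rmp_mv": props.rmp_mv, "r_mohm": props.input_resistance_mohm,
                     "tau_ms": props.tau_ms, "capacitance_pf": props.capacitance_pf,
                     "rheobase_pa": props.rheobase_pa}
                )
        report.tables["intrinsic_properties"] = pd.DataFrame(intrinsic_rows)
        fi = ephys.fi_group_compare(fi_tables)
        report.comparisons.append(
            {
                "name": "fi_two_way_anova",
                "test": "two_way_anova",
                "unit": "cell",
                "statistic": fi["genotype_F"],
                "df": None,
                "p": fi["genotype_p"],
                "n": sum(len(v) for v in fi_tables.values()),
                "flag": _sig_flag(fi["genotype_p"], ALPHA),
            }
        )

        stage = "tracing"
        tc = cfg["tracing"]
        sim = synth.SimConfig(
            seed=seed,
            imaging=synth.ImagingParams(
                process_count=tc["process_count"], soma_count=tc["soma_count"]
            ),
        )
        vol, rois, truth = synth.simulate_tracing_volume(sim, mode="retrograde_sections")
        mask, _thr = tracing.threshold_channel(vol.channel("mCherry"))
        input_rois = [r for name, r in rois.items() if name != "starter-DG"]
        conn = tracing.connectivity_ratio(
            mask, input_rois, rois["starter-DG"], vol.voxel_size_um[1:]
        )
        report.tables["connectivity"] = conn.ranking
        ms_mask = rois["MS"].mask
        coloc = tracing.colocalization_fraction(
            np.where(ms_mask, vol.channel("mCherry"), 0.0),
            vol.channel("GABA"),
            vol.voxel_size_um[1:],
        )
        avol, arois, atruth = synth.simulate_tracing_volume(sim, mode="anterograde_volume")
        dens = tracing.reconstruct_processes_3d(
            avol, arois["hilus"], starter_cell_density=1.0
        )
        report.tables["tracing_summary"] = pd.DataFrame(
            [
                {
                    "mcherry_somata": coloc["n_mcherry"],
                    "gaba_colocalized": coloc["n_colocalized"],
                    "colocalized_fraction": coloc["fraction"],
                    "projection_objects": dens.object_count,
                    "summed_volume_um3": dens.summed_volume_um3,
                    "normalized_density": dens.normalized_density,
                }
            ]
        )
    except Exception as exc:  # noqa: BLE001 - stage attribution contract
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    if out_dir is not None:
        report.write(out_dir)
        if make_figures:
            _write_figures(report, Path(out_dir))
    return report


def _write_figures(report: AnalysisReport, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    if "photometry_summary" in report.tables:
        df = report.tables["photometry_summary"]
        fig, ax = plt.subplots(figsize=(4, 3))
        for i, (g, sub) in enumerate(df.groupby("genotype")):
            ax.scatter([i] * len(sub), sub.event_rate_per_min, label=g)
        ax.set_xticks(range(df.genotype.nunique()))
        ax.set_xticklabels(sorted(df.genotype.unique()))
        ax.set_ylabel("event rate (events/min)")
        fig.tight_layout()
        fig.savefig(fig_dir / "photometry_rates.png", dpi=100)
        plt.close(fig)
    if "coupling" in report.tables:
        df = report.tables["coupling"]
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(df.phase, df.r)
        ax.set_ylabel("Pearson r (MS vs DG)")
        fig.tight_layout()
        fig.savefig(fig_dir / "coupling.png", dpi=100)
        plt.close(fig)
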
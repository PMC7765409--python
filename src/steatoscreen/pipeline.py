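"""End-to-end screen orchestration: simulate -> QC -> call -> confirm -> fit -> profile.

Mirrors the flow of a phenotypic screening campaign: a single-point primary
screen over 384-well plates, retest of primary hits in triplicate at 10 uM
and 1 uM, dose-response confirmation with 4PL fits and potency/selectivity
triage, and fingerprint clustering with target-activity profiling of the
confirmed set. All stages run from one config with one global seed and
write CSV/JSON outputs plus a manifest of counts and file checksums;
re-running an identical config reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .chem import build_activity_matrix, cut_clusters, pairwise_tanimoto, rank_target_classes, ward_cluster
from .dose_response import TriageThresholds, fit_4pl, triage
from .plate_stats import HitThresholds, PlateLayout, call_wells, qc_plate
from .synthetic import (
    DoseSeriesSpec,
    PlateGenParams,
    PlateSpec,
    generate_compound_set,
    generate_dose_series,
    generate_plate,
    ten_point_range,
)

__all__ = ["RunConfig", "RunManifest", "run_screen", "retest_stage"]

STAGES = ("simulate", "qc", "call", "retest", "dose_response", "cluster", "profile")


@dataclass
class RunConfig:
    """Configuration of one screening campaign.

    ``active_fraction`` of compound wells carry a true inhibitor whose IC50
    is drawn log-uniformly from ``active_ic50_range`` (molar); their
    single-point inhibition at the screen concentration follows a hill-1
    binding curve. ``toxic_fraction`` of wells lose ``toxic_cell_loss`` of
    their cells. Unknown config keys are rejected.
    """

    seed: int = 0
    output_dir: str = "runs/screen"
    stages: tuple[str, ...] = STAGES
    n_plates: int = 4
    screen_concentration: float = 10e-6
    active_fraction: float = 0.012
    active_ic50_range: tuple[float, float] = (1e-7, 2e-6)
    toxic_fraction: float = 0.008
    toxic_cell_loss: float = 0.7
    retest_concentrations: tuple[float, float] = (10e-6, 1e-6)
    retest_replicates: int = 3
    retest_confirm_fraction: float = 2.0 / 3.0
    retest_low_dose_inhibition: float = 20.0
    retest_noise_sd: float = 5.0
    dr_replicates: int = 3
    dr_cv: float = 0.1
    cluster_k: int = 3
    activity_cutoff: float = 7.0
    layout: PlateLayout = field(default_factory=PlateLayout)
    thresholds: HitThresholds = field(default_factory=HitThresholds)
    gen: PlateGenParams = field(default_factory=PlateGenParams)
    triage: TriageThresholds = field(default_factory=TriageThresholds)

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        nested = {
            "layout": PlateLayout,
            "thresholds": HitThresholds,
            "gen": PlateGenParams,
            "triage": TriageThresholds,
        }
        kwargs = {}
        for key, sub_cls in nested.items():
            if key in data:
                block = data.pop(key)
                names = {f.name for f in dataclasses.fields(sub_cls)}
                unknown = set(block) - names
                if unknown:
                    raise ValueError(f"unknown keys in {key!r}: {sorted(unknown)}")
                kwargs[key] = sub_cls(**block)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "active_ic50_range", "retest_concentrations"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(io.read_yaml(path) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["active_ic50_range"] = list(self.active_ic50_range)
        d["retest_concentrations"] = list(self.retest_concentrations)
        return d


@dataclass
class RunManifest:
    config: dict
    counts: dict
    checksums: dict
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.to_json() + "\n")
        return path


def _hill1_inhibition(conc: float, ic50: float) -> float:
    """Fractional inhibition of a hill-1 inhibitor at one concentration."""
    if not math.isfinite(ic50):
        return 0.0
    return conc / (conc + ic50)


def simulate_campaign(config: RunConfig):
    """Build the plates and the compound truth table for a campaign.

    Returns (plate tables, truth table). Each compound well holds a distinct
    compound; planted actives get a finite IC50 and their screen-concentration
    inhibition, planted cytotoxics get the configured cell loss.
    """
    rng = np.random.default_rng(config.seed)
    plates = []
    truth_rows = []
    for p in range(config.n_plates):
        plate_id = f"P{p + 1:02d}"
        spec = PlateSpec(
            plate_id=plate_id,
            stim_col=config.layout.stim_col,
            neut_col=config.layout.neut_col,
        )
        wells = spec.compound_wells()
        n_active = int(round(config.active_fraction * len(wells)))
        n_toxic = int(round(config.toxic_fraction * len(wells)))
        picks = rng.choice(len(wells), size=n_active + n_toxic, replace=False)
        active_wells = {wells[i] for i in picks[:n_active]}
        toxic_wells = {wells[i] for i in picks[n_active:]}
        lo, hi = config.active_ic50_range
        inhibition, cell_loss = {}, {}
        for w in wells:
            cid = f"CPD-{plate_id}-{w}"
            if w in active_wells:
                ic50 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                inh = _hill1_inhibition(config.screen_concentration, ic50)
            else:
                ic50, inh = float("inf"), 0.0
            loss = config.toxic_cell_loss if w in toxic_wells else 0.0
            inhibition[w] = inh
            cell_loss[w] = loss
            truth_rows.append(
                {
                    "plate": plate_id,
                    "well": w,
                    "compound": cid,
                    "true_ic50": ic50,
                    "active": w in active_wells,
                    "toxic": w in toxic_wells,
                    "inhibition": inh,
                    "cell_loss": loss,
                }
            )
        spec.inhibition = inhibition
        spec.cell_loss = cell_loss
        summary, _ = generate_plate(
            spec, config.gen, seed=int(rng.integers(0, 2 ** 31 - 1))
        )
        plates.append(summary)
    return plates, pd.DataFrame(truth_rows)


def retest_stage(
    primary_hits: pd.DataFrame,
    concentrations: tuple[float, float] = (10e-6, 1e-6),
    replicates: int = 3,
    confirm_fraction: float = 2.0 / 3.0,
    high_dose_inhibition: float = 50.0,
    low_dose_inhibition: float = 20.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Triplicate retest of primary hits at two concentrations.

    ``primary_hits`` needs columns (compound, true_ic50); measured percent
    inhibition at each concentration is the hill-1 curve value plus Gaussian
    noise. A compound is confirmed when it clears ``high_dose_inhibition``
    in at least ``confirm_fraction`` of high-dose replicates and its mean
    low-dose inhibition reaches ``low_dose_inhibition`` (activity at the low
    dose is what separates dose-dependent inhibitors from single-point
    artifacts).
    """
    if len(primary_hits) == 0:
        raise ValueError("empty primary hit list: nothing to retest")
    high, low = max(concentrations), min(concentrations)
    rng = np.random.default_rng(seed)
    need = math.ceil(confirm_fraction * replicates)
    rows = []
    for _, hit in primary_hits.iterrows():
        ic50 = hit["true_ic50"]
        inh_high = 100.0 * _hill1_inhibition(high, ic50) + rng.normal(0, noise_sd, replicates)
        inh_low = 100.0 * _hill1_inhibition(low, ic50) + rng.normal(0, noise_sd, replicates)
        confirmed = (
            int(np.sum(inh_high >= high_dose_inhibition)) >= need
            and float(inh_low.mean()) >= low_dose_inhibition
        )
        rows.append(
            {
                "compound": hit["compound"],
                "mean_inhibition_high": float(inh_high.mean()),
                "mean_inhibition_low": float(inh_low.mean()),
                "n_high_pass": int(np.sum(inh_high >= high_dose_inhibition)),
                "replicates": replicates,
                "confirmed": bool(confirmed),
            }
        )
    return pd.DataFrame(rows)


def _dose_response_stage(confirmed: pd.DataFrame, config: RunConfig, rng) -> pd.DataFrame:
    rows = []
    for _, cpd in confirmed.iterrows():
        spec = DoseSeriesSpec(
            top=100.0,
            bottom=0.0,
            ic50=float(cpd["true_ic50"]),
            hill=1.0,
            concentrations=ten_point_range(),
            replicates=config.dr_replicates,
            cv=config.dr_cv,
        )
        data = generate_dose_series(spec, seed=int(rng.integers(0, 2 ** 31 - 1)))
        fit = fit_4pl(data["concentration"], data["response"])
        # viability series: flat (no cytotoxicity in the tested range)
        viab_spec = DoseSeriesSpec(
            top=100.0,
            bottom=100.0,
            ic50=1e-3,
            hill=1.0,
            concentrations=ten_point_range(),
            replicates=config.dr_replicates,
            cv=config.dr_cv,
        )
        viab = generate_dose_series(viab_spec, seed=int(rng.integers(0, 2 ** 31 - 1)))
        viab_fit = fit_4pl(viab["concentration"], viab["response"])
        result = triage(fit, viab_fit, config.triage)
        rows.append(
            {
                "compound": cpd["compound"],
                "ic50": fit.ic50,
                "pic50": fit.pic50,
                "hill": fit.hill,
                "converged": fit.converged,
                "censored": fit.censored,
                "active": result.active,
                "selective": result.selective,
                "selectivity_ratio": result.selectivity_ratio,
            }
        )
    return pd.DataFrame(rows)


def run_screen(config: RunConfig, outdir=None) -> RunManifest:
    """Execute the enabled stages in order and write outputs plus a manifest.

    Any stage failure raises an error naming the stage; outputs written by
    earlier stages are retained.
    """
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    counts: dict[str, int] = {}
    files: dict[str, Path] = {}
    plates: list[pd.DataFrame] = []
    truth = calls = confirmed_df = None

    def stage_enabled(name):
        return name in config.stages

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    if stage_enabled("simulate"):
        plates, truth = run_stage("simulate", lambda: simulate_campaign(config))
        summary = pd.concat(plates, ignore_index=True)
        files["well_summaries"] = io.write_table(summary, outdir / "well_summaries.csv")
        files["truth"] = io.write_table(truth, outdir / "truth.csv")
        counts["plates"] = len(plates)
        counts["wells"] = len(summary)
        counts["valid_cells_total"] = int(summary["valid_cell_count"].sum())

    if stage_enabled("qc"):
        if not plates:
            raise RuntimeError("stage 'qc' failed: no plates simulated or loaded")
        qc_rows = [
            dict(plate=p["plate"].iloc[0], **dataclasses.asdict(qc_plate(p, config.layout)))
            for p in plates
        ]
        qc_df = pd.DataFrame(qc_rows)
        files["plate_qc"] = io.write_table(qc_df, outdir / "plate_qc.csv")
        counts["plates_excellent"] = int((qc_df["band"] == "excellent").sum())

    if stage_enabled("call"):
        calls = pd.concat(
            [call_wells(p, config.layout, config.thresholds) for p in plates],
            ignore_index=True,
        )
        calls = calls.merge(truth[["plate", "well", "compound", "true_ic50"]],
                            on=["plate", "well"], how="left")
        files["well_calls"] = io.write_table(calls, outdir / "well_calls.csv")
        counts["hits"] = int((calls["call"] == "hit").sum())
        counts["cytotoxic"] = int((calls["call"] == "cytotoxic").sum())

    if stage_enabled("retest"):
        hits = calls.loc[calls["call"] == "hit"]
        retest = run_stage(
            "retest",
            lambda: retest_stage(
                hits,
                concentrations=config.retest_concentrations,
                replicates=config.retest_replicates,
                confirm_fraction=config.retest_confirm_fraction,
                high_dose_inhibition=config.thresholds.hit_iss,
                low_dose_inhibition=config.retest_low_dose_inhibition,
                noise_sd=config.retest_noise_sd,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            ),
        )
        retest = retest.merge(
            truth[["compound", "true_ic50"]], on="compound", how="left"
        )
        files["retest"] = io.write_table(retest, outdir / "retest.csv")
        counts["confirmed"] = int(retest["confirmed"].sum())
        confirmed_df = retest.loc[retest["confirmed"]]

    if stage_enabled("dose_response"):
        dr = run_stage(
            "dose_response", lambda: _dose_response_stage(confirmed_df, config, rng)
        )
        files["dose_response"] = io.write_table(dr, outdir / "dose_response.csv")
        counts["dose_dependent"] = int(dr["active"].sum()) if len(dr) else 0

    if stage_enabled("cluster") or stage_enabled("profile"):
        n_cpds = max(int(counts.get("confirmed", 0)), 2 * config.cluster_k)
        fps, activities, families, class_map = generate_compound_set(
            n=n_cpds, seed=config.seed + 7, n_families=config.cluster_k
        )
        if stage_enabled("cluster"):
            link = ward_cluster(pairwise_tanimoto(fps), labels=fps.ids)
            labels = cut_clusters(link, k=config.cluster_k)
            cluster_df = pd.DataFrame(
                {"compound": fps.ids, "cluster": labels, "family_truth": families}
            )
            files["clusters"] = io.write_table(cluster_df, outdir / "clusters.csv")
            files["linkage"] = io.write_table(link.to_frame(), outdir / "linkage.csv")
            counts["clusters"] = int(len(set(labels)))
        if stage_enabled("profile"):
            matrix = build_activity_matrix(activities, cutoff=config.activity_cutoff)
            ranking = rank_target_classes(matrix, class_map)
            files["activity_matrix"] = io.write_table(
                matrix.values.reset_index(), outdir / "activity_matrix.csv"
            )
            files["target_classes"] = io.write_table(ranking, outdir / "target_classes.csv")
            counts["active_pairs"] = len(matrix.above_cutoff_pairs())

    manifest = RunManifest(
        config=config.to_dict(),
        counts=counts,
        checksums={k: io.sha256_of(p) for k, p in sorted(files.items())},
    )
    manifest.write(outdir / "manifest.json")
    return manifest
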
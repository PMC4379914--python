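"""End-to-end experiment orchestration.

An :class:`ExperimentPlan` names a set of treatment arms (simulated
cohorts, or track-file manifests for real recordings), the pairwise
comparisons and ANOVA families to run, and optional molecular time
courses.  :func:`run_experiment` simulates or ingests each arm,
extracts the eleven behavioral markers, scores P-sol, and applies the
assay's fixed test-to-marker mapping:

* P-sol          -> Mann–Whitney U (pairwise)
* TDM, FOM       -> Student t (pairwise) or one-way ANOVA + Tukey (families)
* AI             -> Mann–Whitney U (pairwise)
* time courses   -> one-way ANOVA across time points + Tukey

Runs are deterministic under a fixed global seed (arms draw stable
sub-seeds from it) and the emitted report body is byte-identical across
repeated runs; provenance (plan hash, seed, package version) is
embedded in the report.

:func:`scenario_presets` ships frozen synthetic plans emulating the
study designs this pipeline was built around: dopamine-receptor agonist
and antagonist arms, receptor-knockdown arms, isolation time courses
with receptor blockade, and the brain-dopamine / receptor-mRNA time
courses.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arena import GEOMETRY_PRESETS, ArenaGeometry, read_tracks
from .classifier import LogisticModel, fit_logistic, published_model, score_features
from .features import MARKERS, BoutConfig, features_table
from .simulate import (
    CohortSpec,
    TimeCourseSpec,
    blend_params,
    default_phase_params,
    simulate_cohort,
    simulate_timecourse,
)
from .stats import TestResult, mann_whitney_u, one_way_anova, student_t, tukey_hsd

__all__ = [
    "SimulatedArm",
    "FileArm",
    "Comparison",
    "AnovaFamily",
    "ExperimentPlan",
    "RunReport",
    "run_experiment",
    "scenario_presets",
    "plan_from_dict",
    "plan_to_dict",
]

#: Fixed test-to-marker mapping of the analysis plan.
MARKER_TESTS: dict[str, str] = {"P_sol": "mwu", "TDM": "t", "FOM": "t", "AI": "mwu"}


@dataclass(frozen=True)
class SimulatedArm:
    """A treatment arm simulated as a (partial) phase shift.

    ``lam`` interpolates the movement parameters from ``base_phase``
    (0) toward ``blend_target`` (1); a pharmacological or RNAi arm is a
    partial shift, an untreated control is ``lam = 0``.
    """

    label: str
    base_phase: str = "gregarious"
    blend_target: str | None = None
    lam: float = 0.0
    n: int = 30
    duration: float = 360.0
    dt: float = 0.04
    #: explicit cohort seed; when None a stable sub-seed is derived from
    #: the run seed and the arm's position in the plan
    seed: int | None = None


@dataclass(frozen=True)
class FileArm:
    """A treatment arm read from a track-file manifest."""

    label: str
    manifest: str


@dataclass(frozen=True)
class Comparison:
    """Pairwise arm comparison on the given markers (P_sol plus the
    model's retained markers by default)."""

    arm_a: str
    arm_b: str
    markers: tuple[str, ...] = ("P_sol", "TDM", "FOM", "AI")


@dataclass(frozen=True)
class AnovaFamily:
    """A family of arms (e.g. an isolation time course) compared jointly."""

    label: str
    arms: tuple[str, ...]
    markers: tuple[str, ...] = ("TDM", "FOM")


@dataclass(frozen=True)
class ExperimentPlan:
    name: str
    arms: tuple = ()
    comparisons: tuple[Comparison, ...] = ()
    anova_families: tuple[AnovaFamily, ...] = ()
    timecourses: tuple[TimeCourseSpec, ...] = ()
    model_source: str = "published"  # or "refit"
    global_seed: int = 0

    def validate(self) -> None:
        labels = [a.label for a in self.arms]
        if len(set(labels)) != len(labels):
            raise ValueError("arm labels must be unique")
        known = set(labels)
        for c in self.comparisons:
            if c.arm_a not in known or c.arm_b not in known:
                raise ValueError(f"comparison references undefined arm: {c}")
        for fam in self.anova_families:
            missing = [a for a in fam.arms if a not in known]
            if missing:
                raise ValueError(f"anova family {fam.label!r} references {missing}")
        if self.model_source not in ("published", "refit"):
            raise ValueError("model_source must be 'published' or 'refit'")
        tc_labels = [t.label for t in self.timecourses]
        if len(set(tc_labels)) != len(tc_labels):
            raise ValueError("time-course labels must be unique")


@dataclass
class RunReport:
    """Everything one run produced, serialisable to a stable JSON body."""

    plan_name: str
    arm_tables: dict[str, pd.DataFrame]
    arm_summaries: dict[str, dict]
    comparisons: list[dict]
    anova: list[dict]
    timecourses: list[dict]
    provenance: dict

    def body(self) -> dict:
        return {
            "plan": self.plan_name,
            "arm_summaries": self.arm_summaries,
            "comparisons": self.comparisons,
            "anova": self.anova,
            "timecourses": self.timecourses,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.body(), indent=2, sort_keys=True)

    def write(self, output_dir: str | Path) -> Path:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        report_path = output_dir / "report.json"
        report_path.write_text(self.to_json() + "\n")
        for label, table in self.arm_tables.items():
            table.to_csv(output_dir / f"arm_{label}.csv", index=False)
        return report_path


def _plan_hash(plan: ExperimentPlan) -> str:
    payload = json.dumps(plan_to_dict(plan), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _arm_params(arm: SimulatedArm):
    base = default_phase_params(arm.base_phase)
    if arm.blend_target is None:
        return base
    return blend_params(base, default_phase_params(arm.blend_target), arm.lam)


def _quartiles(x: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"q1": float(q1), "median": float(med), "q3": float(q3)}


def _summarise_arm(table: pd.DataFrame) -> dict:
    out = {"n": int(len(table))}
    for col in ("P_sol", "TDM", "FOM", "AI"):
        out[col] = _quartiles(table[col].to_numpy(dtype=float))
    return out


def _reference_model(plan: ExperimentPlan, geom, bout_cfg, seed: int) -> LogisticModel:
    if plan.model_source == "published":
        return published_model()
    # refit on fresh reference cohorts drawn under the plan seed
    tables = []
    for i, phase in enumerate(("gregarious", "solitary")):
        cohort = simulate_cohort(
            CohortSpec(
                n_animals=60,
                params=default_phase_params(phase),
                seed=int(
                    np.random.SeedSequence(entropy=seed, spawn_key=(977, i)).generate_state(1)[0]
                    % (2**31)
                ),
                arm_label=phase,
            ),
            geom,
        )
        tables.append(features_table(cohort, geom, bout_cfg))
    both = pd.concat(tables, ignore_index=True)
    labels = both["arm_label"].to_numpy()
    report = fit_logistic(both, labels, markers=("TDM", "FOM", "AI"))
    return report.model


def _pairwise_tests(
    marker: str, ta: pd.DataFrame, tb: pd.DataFrame, labels: tuple[str, str]
) -> TestResult:
    a = ta[marker].to_numpy(dtype=float)
    b = tb[marker].to_numpy(dtype=float)
    kind = MARKER_TESTS.get(marker, "mwu")
    res = student_t(a, b) if kind == "t" else mann_whitney_u(a, b)
    return replace(res, groups=labels)


def run_experiment(
    plan: ExperimentPlan,
    geometry: ArenaGeometry | str = "open-area",
    bout_cfg: BoutConfig = BoutConfig(),
    output_dir: str | Path | None = None,
    seed: int | None = None,
) -> RunReport:
    """Execute a plan: cohorts -> markers -> P-sol -> comparison battery.

    Deterministic under a fixed seed (``seed`` overrides the plan's
    ``global_seed``); if ``output_dir`` is given the JSON report and
    per-arm feature tables are written there.
    """
    plan.validate()
    geom = GEOMETRY_PRESETS[geometry] if isinstance(geometry, str) else geometry
    run_seed = plan.global_seed if seed is None else int(seed)

    model = _reference_model(plan, geom, bout_cfg, run_seed)

    arm_tables: dict[str, pd.DataFrame] = {}
    for idx, arm in enumerate(plan.arms):
        if isinstance(arm, FileArm):
            trajs = read_tracks(arm.manifest, geom=geom)
            for t in trajs:
                t.arm_label = arm.label
        else:
            if arm.seed is not None:
                sub = int(arm.seed)
            else:
                sub = int(
                    np.random.SeedSequence(entropy=run_seed, spawn_key=(idx,)).generate_state(1)[0]
                    % (2**31)
                )
            spec = CohortSpec(
                n_animals=arm.n,
                params=_arm_params(arm),
                duration=arm.duration,
                dt=arm.dt,
                seed=sub,
                arm_label=arm.label,
            )
            trajs = simulate_cohort(spec, geom)
        table = features_table(trajs, geom, bout_cfg)
        arm_tables[arm.label] = score_features(table, model)

    arm_summaries = {label: _summarise_arm(t) for label, t in arm_tables.items()}

    comparisons: list[dict] = []
    for comp in plan.comparisons:
        ta, tb = arm_tables[comp.arm_a], arm_tables[comp.arm_b]
        for marker in comp.markers:
            res = _pairwise_tests(marker, ta, tb, (comp.arm_a, comp.arm_b))
            entry = res.as_dict()
            entry["marker"] = marker
            comparisons.append(entry)

    anova: list[dict] = []
    for fam in plan.anova_families:
        for marker in fam.markers:
            groups = [arm_tables[a][marker].to_numpy(dtype=float) for a in fam.arms]
            res = one_way_anova(groups)
            entry = res.as_dict()
            entry.update({"family": fam.label, "marker": marker, "arms": list(fam.arms)})
            entry["tukey"] = [
                t.as_dict() for t in tukey_hsd(groups, labels=list(fam.arms))
            ]
            anova.append(entry)

    timecourses: list[dict] = []
    for i, tc in enumerate(plan.timecourses):
        sub = int(
            np.random.SeedSequence(entropy=run_seed, spawn_key=(7000, i)).generate_state(1)[0]
            % (2**31)
        )
        table = simulate_timecourse(replace(tc, seed=sub))
        timecourses.append(analyze_timecourse(table, label=tc.label))

    provenance = {
        "plan_hash": _plan_hash(plan),
        "seed": run_seed,
        "geometry": {
            "open_length_x": geom.open_length_x,
            "width_y": geom.width_y,
            "stimulus_zone_fraction": geom.stimulus_zone_fraction,
            "wall_margin": geom.wall_margin,
        },
        "bout_config": asdict(bout_cfg),
        "model_source": plan.model_source,
        "model": {
            "intercept": model.intercept,
            "coefficients": dict(model.coefficients),
            "threshold": model.threshold,
        },
        "version": __version__,
    }
    report = RunReport(
        plan_name=plan.name,
        arm_tables=arm_tables,
        arm_summaries=arm_summaries,
        comparisons=comparisons,
        anova=anova,
        timecourses=timecourses,
        provenance=provenance,
    )
    if output_dir is not None:
        report.write(output_dir)
    return report


def analyze_timecourse(table: pd.DataFrame, label: str = "") -> dict:
    """ANOVA across time points plus Tukey and a peak fold-change estimate."""
    tps = sorted(table["timepoint"].unique())
    groups = [table.loc[table["timepoint"] == t, "value"].to_numpy(dtype=float) for t in tps]
    res = one_way_anova(groups)
    means = [float(np.mean(g)) for g in groups]
    base = means[0]
    peak_idx = int(np.argmax(means))
    entry = res.as_dict()
    entry.update(
        {
            "label": label,
            "timepoints": [float(t) for t in tps],
            "means": means,
            "fold_change_peak": means[peak_idx] / base,
            "peak_timepoint": float(tps[peak_idx]),
            "tukey": [
                t.as_dict()
                for t in tukey_hsd(groups, labels=[str(float(t)) for t in tps])
            ],
        }
    )
    return entry


# ---------------------------------------------------------------------------
# Frozen synthetic scenario presets.  Blend strengths are the package's own
# calibration of "partial phase shift": controls sit at lam 0, full phase
# references at lam 0; isolation time courses ramp lam with time.
# ---------------------------------------------------------------------------


def _sim(label, base, target=None, lam=0.0, n=30) -> SimulatedArm:
    return SimulatedArm(label=label, base_phase=base, blend_target=target, lam=lam, n=n)


def scenario_presets() -> dict[str, ExperimentPlan]:
    """Named frozen plans emulating the study's experimental designs."""
    presets: dict[str, ExperimentPlan] = {}

    # D1-like receptor activation in solitary animals (agonist arms) and
    # blockade/knockdown in gregarious animals; compared on P-sol.
    presets["dop1-agonist-psol"] = ExperimentPlan(
        name="dop1-agonist-psol",
        arms=(
            _sim("saline-sol", "solitary"),
            _sim("SKF38393-sol", "solitary", "gregarious", 0.45),
            _sim("saline-CS4h", "solitary", "gregarious", 0.3),
            _sim("SKF38393-CS4h", "solitary", "gregarious", 0.7),
            _sim("dsGFP-greg", "gregarious"),
            _sim("dsDop1-greg", "gregarious", "solitary", 0.6),
            _sim("saline-greg", "gregarious"),
            _sim("SCH23390-greg", "gregarious", "solitary", 0.6),
        ),
        comparisons=(
            Comparison("saline-sol", "SKF38393-sol", ("P_sol",)),
            Comparison("saline-CS4h", "SKF38393-CS4h", ("P_sol",)),
            Comparison("dsGFP-greg", "dsDop1-greg", ("P_sol",)),
            Comparison("saline-greg", "SCH23390-greg", ("P_sol",)),
        ),
    )

    # Same arm structure compared on the retained markers TDM/FOM (t test)
    # and AI (Mann-Whitney U).
    presets["dop1-agonist-markers"] = replace(
        presets["dop1-agonist-psol"],
        name="dop1-agonist-markers",
        comparisons=tuple(
            replace(c, markers=("TDM", "FOM", "AI"))
            for c in presets["dop1-agonist-psol"].comparisons
        ),
    )

    # Isolation time course of gregarious animals with D2-like (Dop2)
    # blockade: saline controls solitarise progressively (lam ramps with
    # isolation time); the blockade arm stays gregarious by construction.
    iso_lams = {"0": 0.0, "15": 0.3, "30": 0.6, "60": 0.9}
    saline_arms = tuple(
        _sim(f"saline-IG{t}", "gregarious", "solitary", lam) for t, lam in iso_lams.items()
    )
    sulpiride_arms = tuple(_sim(f"sulpiride-IG{t}", "gregarious") for t in iso_lams)
    presets["dop2-blockade-psol"] = ExperimentPlan(
        name="dop2-blockade-psol",
        arms=saline_arms + sulpiride_arms,
        comparisons=tuple(
            Comparison(f"saline-IG{t}", f"sulpiride-IG{t}", ("P_sol",)) for t in iso_lams
        ),
    )

    presets["dop2-blockade-markers"] = ExperimentPlan(
        name="dop2-blockade-markers",
        arms=saline_arms + sulpiride_arms,
        comparisons=(
            Comparison("saline-IG0", "saline-IG60", ("AI",)),
            Comparison("sulpiride-IG0", "sulpiride-IG60", ("AI",)),
        ),
        anova_families=(
            AnovaFamily("saline-isolation", tuple(a.label for a in saline_arms)),
            AnovaFamily("sulpiride-isolation", tuple(a.label for a in sulpiride_arms)),
        ),
    )

    # Brain dopamine concentration during crowding and isolation
    # (ng/brain; rises toward 4 h of crowding, falls within 1 h of
    # isolation), eight replicates per time point.
    presets["da-timecourse"] = ExperimentPlan(
        name="da-timecourse",
        timecourses=(
            TimeCourseSpec(
                timepoints=(0.0, 1.0, 4.0, 16.0, 32.0),
                mean_profile=(1.2, 1.4, 2.2, 1.7, 1.4),
                label="DA-crowding",
            ),
            TimeCourseSpec(
                timepoints=(0.0, 1.0, 4.0, 16.0, 32.0),
                mean_profile=(2.2, 1.3, 1.2, 1.1, 1.0),
                label="DA-isolation",
            ),
        ),
    )

    # Receptor mRNA levels: Dop1 rises ~5-fold at 4 h of crowding and is
    # flat in isolation; Dop2 is flat in crowding and rises in isolation.
    presets["receptor-mrna-timecourse"] = ExperimentPlan(
        name="receptor-mrna-timecourse",
        timecourses=(
            TimeCourseSpec(mean_profile=(1.0, 2.0, 5.0, 3.0, 2.0), label="Dop1-crowding"),
            TimeCourseSpec(mean_profile=(1.0, 1.0, 1.1, 1.0, 1.0), label="Dop1-isolation"),
            TimeCourseSpec(mean_profile=(1.0, 1.1, 1.0, 1.0, 1.1), label="Dop2-crowding"),
            TimeCourseSpec(mean_profile=(1.0, 2.4, 2.2, 2.3, 2.4), label="Dop2-isolation"),
        ),
    )

    # Gregarious-vs-solitary reference contrast scored with the published
    # model; the canonical two-arm run.
    presets["phase-reference"] = ExperimentPlan(
        name="phase-reference",
        arms=(_sim("gregarious", "gregarious"), _sim("solitary", "solitary")),
        comparisons=(Comparison("gregarious", "solitary"),),
    )

    for plan in presets.values():
        plan.validate()
    return presets


# ---------------------------------------------------------------------------
# Plan (de)serialisation for config files.
# ---------------------------------------------------------------------------


def plan_to_dict(plan: ExperimentPlan) -> dict:
    def arm_dict(a):
        d = asdict(a)
        d["kind"] = "file" if isinstance(a, FileArm) else "simulated"
        return d

    return {
        "name": plan.name,
        "arms": [arm_dict(a) for a in plan.arms],
        "comparisons": [asdict(c) | {"markers": list(c.markers)} for c in plan.comparisons],
        "anova_families": [
            asdict(f) | {"arms": list(f.arms), "markers": list(f.markers)}
            for f in plan.anova_families
        ],
        "timecourses": [
            asdict(t)
            | {"timepoints": list(t.timepoints), "mean_profile": list(t.mean_profile)}
            for t in plan.timecourses
        ],
        "model_source": plan.model_source,
        "global_seed": plan.global_seed,
    }


def plan_from_dict(payload: Mapping) -> ExperimentPlan:
    arms = []
    for a in payload.get("arms", ()):
        a = dict(a)
        kind = a.pop("kind", "simulated")
        arms.append(FileArm(**a) if kind == "file" else SimulatedArm(**a))
    comparisons = tuple(
        Comparison(c["arm_a"], c["arm_b"], tuple(c.get("markers", ("P_sol", "TDM", "FOM", "AI"))))
        for c in payload.get("comparisons", ())
    )
    families = tuple(
        AnovaFamily(f["label"], tuple(f["arms"]), tuple(f.get("markers", ("TDM", "FOM"))))
        for f in payload.get("anova_families", ())
    )
    tcs = tuple(
        TimeCourseSpec(
            timepoints=tuple(t.get("timepoints", (0.0, 1.0, 4.0, 16.0, 32.0))),
            mean_profile=tuple(t["mean_profile"]),
            cv=float(t.get("cv", 0.2)),
            n_per_point=int(t.get("n_per_point", 8)),
            seed=int(t.get("seed", 0)),
            label=str(t.get("label", "")),
        )
        for t in payload.get("timecourses", ())
    )
    plan = ExperimentPlan(
        name=str(payload.get("name", "experiment")),
        arms=tuple(arms),
        comparisons=comparisons,
        anova_families=families,
        timecourses=tcs,
        model_source=str(payload.get("model_source", "published")),
        global_seed=int(payload.get("global_seed", 0)),
    )
    plan.validate()
    return plan


def load_plan(path: str | Path) -> ExperimentPlan:
    with open(path) as fh:
        return plan_from_dict(yaml.safe_load(fh))
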
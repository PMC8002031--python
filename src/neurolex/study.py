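"""End-to-end study replica: simulate -> exclude -> ERP/MSE -> task PLS -> behaviour.

One call runs the eight analysis families of the design — {ERP, MSE}
features x {across-session (3 conditions), within-session segments (10
conditions, one analysis per session)} — plus the behavioural ANOVA
chain, from a single seed.  Across-session analyses are tested at
alpha = .05, within-session at the Bonferroni-corrected alpha = .008.

Participants are simulated and reduced to feature vectors one at a time,
so the full epochs tensor is never held in memory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behaviour import build_behavioural_table, paired_followups, rm_anova_2x3
from .entropy import MseParams, mse_trials
from .epochs import (EpochSet, average_erp, exclude_incorrect,
                     exclude_rt_outliers, partition_segments)
from .pls import PlsInput, PlsResult, run_task_pls
from .simulate import SimulationConfig, simulate_participant

__all__ = ["StudyConfig", "StudyReport", "collect_session_features",
           "erp_feature_index", "mse_feature_index", "run_study"]


@dataclass(frozen=True)
class StudyConfig:
    """Settings for one full study run.

    ``outliers_before_accuracy`` controls the exclusion order (RT-outlier
    rule on all trials first, then incorrect-trial removal — the
    documented default); flipping it applies the RT rule to correct
    trials only.
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    mse: MseParams = field(default_factory=MseParams)
    n_perm: int = 500
    n_boot: int = 500
    bsr_threshold: float = 2.0
    alpha_across: float = 0.05
    alpha_within: float = 0.008
    min_run_ms: float = 10.0
    n_segments: int = 10
    mse_window: str = "full"
    compute_erp: bool = True
    compute_mse: bool = True
    outliers_before_accuracy: bool = True
    seed: int | None = None

    def master_seed(self) -> int:
        return self.sim.rng_seed if self.seed is None else self.seed

    def config_hash(self) -> str:
        return hashlib.sha1(repr(asdict(self)).encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    families: dict
    behaviour: dict
    exclusions: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps({
            "provenance": self.provenance,
            "exclusions": self.exclusions,
            "behaviour": self.behaviour,
            "families": {
                name: {k: v for k, v in fam.items() if k != "pls"}
                for name, fam in self.families.items()
            },
        }, indent=2, default=_jsonable)

    def to_markdown(self) -> str:
        lines = ["# Study report", "",
                 f"seed {self.provenance['seed']}, config {self.provenance['config_hash']}",
                 "", "## Analysis families", ""]
        for name, fam in self.families.items():
            if not fam["run"]:
                lines.append(f"- **{name}**: skipped")
                continue
            sig = fam.get("significant_lvs")
            lines.append(f"- **{name}**: {fam['n_lvs']} LVs"
                         + (f", significant: {sig}" if sig is not None else
                            " (descriptive only)"))
        lines += ["", "## Behaviour", ""]
        for dv, res in self.behaviour.items():
            for row in res["anova"]:
                lines.append(f"- {dv} {row['effect']}: F({row['df1']:.2f},"
                             f"{row['df2']:.2f}) = {row['F']:.2f}, "
                             f"p = {row['p_reported']:.4f}, ng2 = {row['ng2']:.3f}")
        return "\n".join(lines) + "\n"


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def erp_feature_index(channel_labels, times_ms) -> pd.DataFrame:
    """Column index for flattened channel x timepoint ERP features."""
    return pd.DataFrame({
        "channel": np.repeat(channel_labels, len(times_ms)),
        "position": np.tile(np.asarray(times_ms, dtype=float), len(channel_labels)),
    })


def mse_feature_index(channel_labels, scale_window_ms) -> pd.DataFrame:
    """Column index for flattened channel x scale entropy features
    (position = coarse-graining window length in ms)."""
    return pd.DataFrame({
        "channel": np.repeat(channel_labels, len(scale_window_ms)),
        "position": np.tile(np.asarray(scale_window_ms, dtype=float),
                            len(channel_labels)),
    })


def collect_session_features(sim: SimulationConfig, feature: str = "erp",
                             mse_params: MseParams | None = None,
                             mse_window: str = "full",
                             outliers_first: bool = True) -> PlsInput:
    """Simulate, apply exclusions, and build the across-session PLS input.

    Per participant and session the retained (outlier-free, correct)
    trials are reduced to one feature vector: the baseline-corrected ERP
    (channel x timepoint) or the trial-averaged entropy matrix
    (channel x scale).  Returns a PlsInput with 3 session conditions.
    """
    if feature not in ("erp", "mse"):
        raise ValueError("feature must be 'erp' or 'mse'")
    mse_params = mse_params or MseParams()
    stacks, index = [], None
    for p in range(1, sim.n_participants + 1):
        sess_epochs, log = simulate_participant(sim, p)
        retained, _ = _apply_exclusions(log, outliers_first)
        feats = []
        for s in range(1, sim.n_sessions + 1):
            ep = _retained_epochs(sess_epochs[s], retained[retained.session == s])
            if feature == "erp":
                feats.append(average_erp(ep).mean.ravel())
                if index is None:
                    index = erp_feature_index(ep.channel_labels, ep.times_ms)
            else:
                ent = mse_trials(ep, mse_params, window=mse_window)
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore", RuntimeWarning)
                    feats.append(np.nanmean(ent, axis=0).ravel())
                if index is None:
                    index = mse_feature_index(
                        ep.channel_labels,
                        mse_params.scale_window_ms(ep.sampling_rate))
        stacks.append(np.stack(feats))
    return PlsInput.from_stack(np.stack(stacks, axis=1), feature_index=index,
                               drop_nan_columns=(feature == "mse"))


def _retained_epochs(epochs: EpochSet, retained: pd.DataFrame) -> EpochSet:
    mask = epochs.trial_meta["trial"].isin(retained["trial"]).to_numpy()
    return epochs.select(mask)


def _apply_exclusions(log: pd.DataFrame, outliers_first: bool = True
                      ) -> tuple[pd.DataFrame, dict]:
    if outliers_first:
        kept, report = exclude_rt_outliers(log)
        n_out = len(log) - len(kept)
        final = exclude_incorrect(kept)
        n_inc = len(kept) - len(final)
    else:
        correct = exclude_incorrect(log)
        n_inc = len(log) - len(correct)
        final, report = exclude_rt_outliers(correct)
        n_out = len(correct) - len(final)
    stats = {"n_total": len(log),
             "n_rt_outliers": int(n_out),
             "pct_rt_outliers": 100.0 * n_out / len(log),
             "n_incorrect": int(n_inc),
             "n_retained": len(final)}
    return final, stats


def _family_entry(res: PlsResult | None, alpha: float | None) -> dict:
    if res is None:
        return {"run": False}
    entry = {
        "run": True,
        "n_lvs": len(res.lvs),
        "singular_values": [lv.singular_value for lv in res.lvs],
        "covariance_explained": [lv.covariance_explained for lv in res.lvs],
        "perm_p": [lv.perm_p for lv in res.lvs],
        "design_saliences_lv1": (res.lvs[0].design_saliences.tolist()
                                 if res.lvs else []),
        "pls": res,
    }
    if res.n_perm > 0 and alpha is not None:
        entry["alpha"] = alpha
        entry["significant_lvs"] = [k + 1 for k, lv in enumerate(res.lvs)
                                    if lv.perm_p is not None and lv.perm_p < alpha]
    else:
        entry["significant_lvs"] = None
    if res.stable_windows is not None:
        entry["n_stable_windows_lv1"] = int(
            (res.stable_windows["lv"] == 1).sum())
    return entry


def run_study(config: StudyConfig, out_dir=None) -> StudyReport:
    """Run the full replica; deterministic under a fixed seed.

    Returns a StudyReport; with ``out_dir`` the JSON/Markdown report and
    per-family salience, bootstrap-ratio and stable-window CSVs are
    written alongside the behavioural tables.
    """
    sim = replace(config.sim, rng_seed=config.master_seed())
    sim.validate()
    seed_seq = np.random.SeedSequence(entropy=config.master_seed(), spawn_key=(10_000,))
    family_seeds = {name: s for name, s in zip(
        ["erp_across", "erp_within_1", "erp_within_2", "erp_within_3",
         "mse_across", "mse_within_1", "mse_within_2", "mse_within_3"],
        seed_seq.spawn(8))}

    n_sessions = sim.n_sessions
    k_seg = config.n_segments
    subjects = range(1, sim.n_participants + 1)

    erp_across, mse_across = [], []          # per subject: (n_sessions, F)
    erp_within = {s: [] for s in range(1, n_sessions + 1)}   # (k_seg, F) each
    mse_within = {s: [] for s in range(1, n_sessions + 1)}
    logs, erp_index, mse_index = [], None, None
    undefined_mse_cells = 0

    for p in subjects:
        sess_epochs, log = simulate_participant(sim, p)
        logs.append(log)
        retained, _ = _apply_exclusions(log, config.outliers_before_accuracy)
        erp_sess, mse_sess = [], []
        for s in range(1, n_sessions + 1):
            ep = _retained_epochs(sess_epochs[s], retained[retained.session == s])
            if ep.n_trials < k_seg:
                raise ValueError(
                    f"participant {p} session {s}: only {ep.n_trials} retained "
                    f"trials, cannot form {k_seg} segments")
            seg = partition_segments(ep.n_trials, k_seg)
            if config.compute_erp:
                erp = average_erp(ep, condition=f"sub{p}_ses{s}")
                erp_sess.append(erp.mean.ravel())
                erp_within[s].append(np.stack([
                    average_erp(ep.select(seg == g)).mean.ravel()
                    for g in range(1, k_seg + 1)]))
                if erp_index is None:
                    erp_index = erp_feature_index(ep.channel_labels, ep.times_ms)
            if config.compute_mse:
                ent = mse_trials(ep, config.mse, window=config.mse_window)
                undefined_mse_cells += int(np.isnan(ent).sum())
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore", RuntimeWarning)
                    mse_sess.append(np.nanmean(ent, axis=0).ravel())
                    mse_within[s].append(np.stack([
                        np.nanmean(ent[seg == g], axis=0).ravel()
                        for g in range(1, k_seg + 1)]))
                if mse_index is None:
                    mse_index = mse_feature_index(
                        ep.channel_labels,
                        config.mse.scale_window_ms(ep.sampling_rate))
        if config.compute_erp:
            erp_across.append(np.stack(erp_sess))
        if config.compute_mse:
            mse_across.append(np.stack(mse_sess))

    full_log = pd.concat(logs, ignore_index=True)

    def _pls(stacks, index, seed_key, alpha, scale_features):
        # stacks: list over subjects of (n_cond, F)
        arr = np.stack(stacks, axis=1)       # (n_cond, n_subj, F)
        inp = PlsInput.from_stack(arr, feature_index=index,
                                  drop_nan_columns=scale_features)
        rng = np.random.default_rng(family_seeds[seed_key])
        return run_task_pls(inp, n_perm=config.n_perm, n_boot=config.n_boot,
                            rng=rng, bsr_threshold=config.bsr_threshold,
                            min_run_ms=config.min_run_ms,
                            scale_features=scale_features)

    families: dict[str, dict] = {}
    for feat, on, across, within, index in (
            ("erp", config.compute_erp, erp_across, erp_within, erp_index),
            ("mse", config.compute_mse, mse_across, mse_within, mse_index)):
        scale_features = feat == "mse"
        name = f"{feat}_across"
        families[name] = (_family_entry(
            _pls(across, index, name, config.alpha_across, scale_features),
            config.alpha_across) if on else {"run": False})
        for s in range(1, n_sessions + 1):
            name = f"{feat}_within_{s}"
            families[name] = (_family_entry(
                _pls(within[s], index, name, config.alpha_within, scale_features),
                config.alpha_within) if on else {"run": False})

    # behavioural chain
    retained_all, excl = _apply_exclusions(full_log, config.outliers_before_accuracy)
    table = build_behavioural_table(full_log)
    behaviour = {}
    for dv in ("rt_ms", "accuracy"):
        res = rm_anova_2x3(table, dv=dv)
        interaction_sig = bool(res.table.iloc[2]["p_reported"] < 0.05)
        entry = {"anova": res.table.to_dict("records"),
                 "interaction_significant": interaction_sig}
        if interaction_sig:
            entry["followups"] = {
                lex: paired_followups(table, dv=dv, subset={"lexicality": lex},
                                      alpha=0.017).to_dict("records")
                for lex in table["lexicality"].unique()}
        behaviour[dv] = entry

    excl["undefined_mse_cells"] = undefined_mse_cells
    report = StudyReport(
        families=families,
        behaviour=behaviour,
        exclusions=excl,
        provenance={"seed": config.master_seed(),
                    "config_hash": config.config_hash(),
                    "package_version": __version__,
                    "n_participants": sim.n_participants,
                    "n_perm": config.n_perm, "n_boot": config.n_boot},
    )
    if out_dir is not None:
        _persist(report, table, Path(out_dir))
    return report


def _persist(report: StudyReport, behav_table: pd.DataFrame, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    (out / "report.md").write_text(report.to_markdown())
    behav_table.to_csv(out / "behaviour_table.csv", index=False)
    for name, fam in report.families.items():
        res: PlsResult | None = fam.get("pls")
        if res is None or not res.lvs:
            continue
        res.summary().to_csv(out / f"{name}_lvs.csv", index=False)
        sal = pd.DataFrame(
            {f"lv{k+1}": lv.feature_saliences for k, lv in enumerate(res.lvs)})
        if res.input.feature_index is not None:
            sal = pd.concat([res.input.feature_index, sal], axis=1)
        sal.to_csv(out / f"{name}_feature_saliences.csv", index=False)
        if res.lvs[0].bootstrap_ratios is not None:
            bsr = pd.DataFrame(
                {f"lv{k+1}": lv.bootstrap_ratios for k, lv in enumerate(res.lvs)})
            if res.input.feature_index is not None:
                bsr = pd.concat([res.input.feature_index, bsr], axis=1)
            bsr.to_csv(out / f"{name}_bootstrap_ratios.csv", index=False)
        if res.stable_windows is not None:
            res.stable_windows.to_csv(out / f"{name}_stable_windows.csv", index=False)
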
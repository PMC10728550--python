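"""End-to-end orchestration: simulate -> rates -> coding -> decoding ->
cross-temporal -> assemblies -> rhythm -> report.

Every stage writes plain CSV/JSON next to a resolved copy of the
configuration and the master seed, so any stage can be inspected or rerun
in isolation.  All randomness derives from the master seed through spawned
``SeedSequence`` children, one per stage, making a run fully reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import assembly as asm
from . import cross_temporal as ct
from . import decoding as dec
from . import rhythm as rhy
from . import single_unit as su
from .core import Session, select_units, write_session
from .rates import build_rate_tensor, select_bandwidths
from .synthetic import GeneratorConfig, generate_session, write_truth

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "rates",
    "unit_coding",
    "decode",
    "cross_temporal",
    "assemblies",
    "rhythm",
    "report",
)


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    simulate: dict = field(default_factory=dict)  # GeneratorConfig overrides
    spikes_path: str | None = None  # load instead of simulate
    events_path: str | None = None
    min_rate_hz: float = 0.5
    lam: float = 0.05
    bin_s: float = 0.05
    sample_window: tuple[float, float] = (5.0, 5.0)
    n_shuffle: int = 1000
    n_boot_fa: int = 500
    max_factors: int = 6
    n_resamples_ct: int = 500
    n_per_class_ct: int = 8
    ct_stride: int = 2  # decode every ct_stride-th bin in the grid
    n_ccg_draws: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "sample_window" in raw:
            raw["sample_window"] = tuple(raw["sample_window"])
        return cls(**raw)


class StageError(RuntimeError):
    pass


def _labels(trials) -> np.ndarray:
    return np.asarray([t.cue_side for t in trials])


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Execute the configured stages; returns the summary dictionary.

    Outputs land under ``out_dir``; a stage failure halts the run with the
    stage named, keeping partial outputs on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(ALL_STAGES))
    stage_seed = {name: s for name, s in zip(ALL_STAGES, seeds)}
    summary: dict = {"seed": cfg.seed, "stages": {}}
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=1, default=str)
    )

    session: Session | None = None
    truth = None
    state: dict = {}

    def timed(name):
        t0 = time.perf_counter()

        def done(**info):
            summary["stages"][name] = {
                "elapsed_s": round(time.perf_counter() - t0, 3),
                **info,
            }

        return done

    try:
        # ------------------------------------------------------------ simulate
        if "simulate" in cfg.stages:
            fin = timed("simulate")
            gen_cfg = GeneratorConfig(
                **{**cfg.simulate, "seed": int(stage_seed["simulate"].generate_state(1)[0] % (2**31))}
            )
            session, truth = generate_session(gen_cfg)
            write_session(session, out / "spikes.csv", out / "events.csv")
            write_truth(truth, out / "truth.json")
            fin(n_units=len(session.units), n_trials=len(session.trials))
        elif cfg.spikes_path and cfg.events_path:
            from .core import read_session

            session = read_session(cfg.spikes_path, cfg.events_path)
        if session is None:
            raise StageError("no session: enable 'simulate' or give input paths")

        session = select_units(session, cfg.min_rate_hz)
        correct = [t for t in session.completed_trials() if t.outcome == "correct"]
        errors = [t for t in session.completed_trials() if t.outcome == "error"]

        # --------------------------------------------------------------- rates
        if "rates" in cfg.stages:
            fin = timed("rates")
            bandwidths = select_bandwidths(session)
            state["bandwidths"] = bandwidths
            import pandas as pd

            pd.DataFrame(
                [(u, h) for u, h in bandwidths.items()],
                columns=["unit_id", "bandwidth_s"],
            ).to_csv(out / "bandwidths.csv", index=False)
            state["tensor_sample"] = build_rate_tensor(
                session, "sample", cfg.sample_window, cfg.bin_s, bandwidths, correct
            )
            state["tensor_choice"] = build_rate_tensor(
                session, "choice", cfg.sample_window, cfg.bin_s, bandwidths, correct
            )
            fin(median_bandwidth_s=float(np.median(list(bandwidths.values()))))

        # --------------------------------------------------------- unit coding
        if "unit_coding" in cfg.stages:
            if "tensor_sample" not in state:
                raise StageError("unit_coding requires the rates stage")
            fin = timed("unit_coding")
            rng = np.random.default_rng(stage_seed["unit_coding"])
            tens = state["tensor_sample"]
            labels = _labels(correct)
            report = su.unit_report(tens, labels, n_shuffle=cfg.n_shuffle, rng=rng)
            report["informative"] = report["duration_s"] > cfg.bin_s
            report.to_csv(out / "unit_report.csv", index=False)
            by_area = report.groupby("area")["peak_t"].mean().to_dict()
            fin(
                mean_peak_t=by_area,
                frac_informative=float(report["informative"].mean()),
            )
            state["unit_report"] = report

        # -------------------------------------------------------------- decode
        if "decode" in cfg.stages:
            if "tensor_sample" not in state:
                raise StageError("decode requires the rates stage")
            fin = timed("decode")
            rng = np.random.default_rng(stage_seed["decode"])
            tens = state["tensor_sample"]
            labels = _labels(correct)
            per_area = dec.equalize_and_decode(tens, labels, cfg.lam, rng=rng)
            import pandas as pd

            rows = {"time_s": tens.times}
            for area, res in per_area.items():
                rows[f"cp_{area}"] = res.cp
            pd.DataFrame(rows).to_csv(out / "decode_sample.csv", index=False)
            info = {a: float(np.max(r.cp)) for a, r in per_area.items()}
            state["decode_sample"] = per_area
            if len(errors) >= 3:
                tens_err = build_rate_tensor(
                    session, "sample", cfg.sample_window, cfg.bin_s,
                    state["bandwidths"], errors,
                )
                err_res, corr_res = dec.train_correct_test_error(
                    tens, tens_err, labels, _labels(errors), cfg.lam,
                    n_perm=200, rng=rng,
                )
                state["decode_error"] = (err_res, corr_res)
                info["error_cp_min"] = float(np.min(err_res.cp))
            fin(peak_cp=info)

        # ------------------------------------------------------ cross-temporal
        if "cross_temporal" in cfg.stages:
            if "tensor_sample" not in state:
                raise StageError("cross_temporal requires the rates stage")
            fin = timed("cross_temporal")
            rng = np.random.default_rng(stage_seed["cross_temporal"])
            tens = state["tensor_sample"]
            sub = tens.rates[:, :, :: cfg.ct_stride]
            from .core import AlignedRateTensor

            tcoarse = AlignedRateTensor(
                rates=sub, times=tens.times[:: cfg.ct_stride],
                bin_s=tens.bin_s * cfg.ct_stride, align_event=tens.align_event,
                unit_ids=tens.unit_ids, trial_indices=tens.trial_indices,
                areas=tens.areas,
            )
            mat = ct.cross_temporal_decode(
                tcoarse, _labels(correct), cfg.n_per_class_ct,
                cfg.n_resamples_ct, cfg.lam, rng,
            )
            np.savetxt(out / "ct_grid.csv", mat.perf, delimiter=",")
            (out / "ct_grid.json").write_text(
                json.dumps(
                    {
                        "train_times": mat.train_times.tolist(),
                        "n_resamples": cfg.n_resamples_ct,
                        "n_per_class": cfg.n_per_class_ct,
                    }
                )
            )
            state["ct"] = mat
            fin(mean_diag=float(np.mean(mat.diagonal)))

        # ---------------------------------------------------------- assemblies
        if "assemblies" in cfg.stages:
            fin = timed("assemblies")
            rng = np.random.default_rng(stage_seed["assemblies"])
            X, owners, uids = asm.build_fa_input(session, "joint")
            areas = {u.unit_id: u.area for u in session.units}
            groups = asm.shuffle_groups(session)
            p_sig = asm.select_n_factors(
                X, owners, cfg.max_factors, n_boot=cfg.n_boot_fa, rng=rng,
                groups=groups,
            )
            assemblies = []
            if p_sig > 0:
                model = asm.fit_fa(X, p_sig, ridge=asm.DEFAULT_RIDGE)
                boot = asm.bootstrap_loadings(
                    X, owners, p_sig, cfg.n_boot_fa, rng, groups=groups,
                    ridge=asm.DEFAULT_RIDGE,
                )
                mask = asm.significant_loadings(model, boot)
                assemblies = asm.assemble(mask, uids, areas)
                act_mask = asm.activation_significance(
                    model, X, owners, rng=rng, groups=groups
                )
                scores = model.scores(X)
                for a in assemblies:
                    a.activation = scores[a.factor_index]
                    a.sig_activation_mask = act_mask[a.factor_index]
                np.savetxt(out / "activations.csv", scores.T, delimiter=",")
                state["fa_model"] = model
                state["fa_X"] = (X, owners, uids)
            Xc, _, uids_c = asm.build_count_input(session)
            ica = asm.ica_assemblies(
                Xc, uids_c, areas,
                seed=int(stage_seed["assemblies"].generate_state(1)[0] % (2**31)),
            )
            state["assemblies"] = assemblies
            (out / "assemblies.json").write_text(
                json.dumps(
                    {
                        "n_factors": p_sig,
                        "assemblies": [
                            {
                                "id": a.id,
                                "members": a.member_units,
                                "type": a.kind,
                                "factor": a.factor_index,
                            }
                            for a in assemblies
                        ],
                        "ica_assemblies": [
                            {"id": a.id, "members": a.member_units, "type": a.kind}
                            for a in ica
                        ],
                        "fa_ica_overlap": asm.match_overlap(assemblies, ica),
                    },
                    indent=1,
                )
            )
            fin(n_factors=p_sig, n_assemblies=len(assemblies),
                fa_ica_overlap=asm.match_overlap(assemblies, ica))

        # -------------------------------------------------------------- rhythm
        if "rhythm" in cfg.stages:
            fin = timed("rhythm")
            rng = np.random.default_rng(stage_seed["rhythm"])
            assemblies = state.get("assemblies", [])
            inter = [a for a in assemblies if a.kind == "inter-area"]
            sample_times = np.array([t.t_sample for t in correct])
            pairs_rows = []
            members = {u for a in inter for u in a.member_units}
            units = {u.unit_id: u for u in session.units}
            epochs = [(t - 4.0, t) for t in sample_times]
            ca1 = [u for u in session.units_in("dCA1")]
            pfc = [u for u in session.units_in("mPFC")]
            for uc in ca1[:10]:
                for um in pfc[:10]:
                    same = uc.unit_id in members and um.unit_id in members
                    _, _, band = rhy.pair_coherence(
                        uc.spike_times, um.spike_times, epochs
                    )
                    ccg = rhy.crosscorrelogram(
                        uc.spike_times, um.spike_times, sample_times,
                        n_draws=cfg.n_ccg_draws, rng=rng,
                    )
                    pairs_rows.append(
                        {
                            "unit_a": uc.unit_id,
                            "unit_b": um.unit_id,
                            "same_assembly": same,
                            "band_coherence": band,
                            "lead_lag": rhy.lead_lag_balance(ccg) if ccg else np.nan,
                        }
                    )
            import pandas as pd

            dfp = pd.DataFrame(pairs_rows)
            dfp.to_csv(out / "pairs.csv", index=False)
            info = {}
            if dfp["same_assembly"].any():
                info["member_band_coherence"] = float(
                    dfp.loc[dfp.same_assembly, "band_coherence"].mean()
                )
                info["nonmember_band_coherence"] = float(
                    dfp.loc[~dfp.same_assembly, "band_coherence"].mean()
                )
            fin(**info)

        # -------------------------------------------------------------- report
        if "report" in cfg.stages:
            fin = timed("report")
            fin()
            (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
            lines = ["# Pipeline run summary", ""]
            for name, info in summary["stages"].items():
                lines.append(f"- **{name}**: {json.dumps(info, default=float)}")
            (out / "summary.md").write_text("\n".join(lines))
    except StageError:
        raise
    except Exception as e:  # halt with stage context
        done_stages = list(summary["stages"])
        raise StageError(
            f"pipeline failed after stages {done_stages}: {e}"
        ) from e
    return summary
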
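"""Configuration-driven synthetic experiment: simulate treatment groups,
extract features, decompose AP currents, run voltage-clamp isolation, call
AIS profiles, and compare groups statistically.

The treatment effect of chronic muscarinic blockade is modeled as an
increase of the maximal A-type conductance (``g_A_scale`` per group),
optionally with AIS elongation (``ais_length_scale``); cell-to-cell
variability is lognormal jitter on the conductances.  Every stage is
seeded deterministically from the experiment seed, and a manifest with the
configuration echo and SHA-256 hashes of all outputs is written so a rerun
can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ais import measure_ais
from .apcurrent import net_ion_current
from .model import NeuronModel, apply_pharmacology
from .protocol import current_step_protocol, voltage_step_protocol
from .simulate import simulate_neuron, synth_ais_profile
from .spikes import ap_features, fi_curve, passive_props, sweep_features
from .stats import compare_fi, compare_groups, make_group_table
from .vclamp import fit_boltzmann, gv_from_iv, measure_iv, subtract_currents
from .io import write_table

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

log = logging.getLogger("ephysdecomp.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": "ephysdecomp_run",
    "n_cells": 4,
    "param_jitter_cv": 0.05,
    "noise_sd_mv": 0.2,
    "groups": {
        "control": {"g_A_scale": 1.0},
        "atropine-0-10DIV": {"g_A_scale": 1.8, "ais_length_scale": 1.25},
    },
    "model": {},  # NeuronModel field overrides
    "protocol": {},  # current_step_protocol overrides
    "analyses": ["features", "apcurrent", "vclamp", "ais", "stats"],
    "ais": {"start_um": 5.0, "length_um": 20.0, "edge_sd_um": 1.0,
            "noise_sd": 20.0, "step_um": 0.1},
}


def load_config(path_or_dict) -> dict:
    """Load a YAML config file (or pass a dict) and merge with defaults."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as f:
            user = yaml.safe_load(f) or {}
    else:
        user = dict(path_or_dict)
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict) and k != "groups":
            cfg[k].update(v)
        else:
            cfg[k] = v
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    if not cfg["groups"]:
        raise ValueError("config needs at least one group")
    for g, spec in cfg["groups"].items():
        if not isinstance(spec, dict):
            raise ValueError(f"group {g!r} must map to a dict of model scalings")
    if "seed" not in cfg:
        raise ValueError("config must set an explicit seed")
    if int(cfg["n_cells"]) < 1:
        raise ValueError("n_cells must be >= 1")


def _cell_seed(base_seed: int, gi: int, ci: int) -> int:
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(gi, ci))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _jitter_model(model: NeuronModel, cv: float, rng: np.random.Generator) -> NeuronModel:
    if cv <= 0:
        return model
    sigma2 = np.log1p(cv**2)
    fields = {}
    for name in ("g_Na", "g_DR", "g_A", "g_L"):
        factor = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2))
        fields[name] = getattr(model, name) * factor
    return model.with_(**fields)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config, out_dir=None) -> Path:
    """Run the full synthetic experiment; returns the report directory."""
    cfg = load_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    base_seed = int(cfg["seed"])
    analyses = set(cfg["analyses"])

    base_model = NeuronModel(**cfg["model"])
    proto = current_step_protocol(**cfg["protocol"])

    feature_rows = []  # (cell_id, culture_id, group, feature, value)
    fi_rows = []
    ais_rows = []
    vc_fits = {}
    written: list[Path] = []

    for gi, (group, gspec) in enumerate(sorted(cfg["groups"].items())):
        g_model = base_model.with_(g_A=base_model.g_A * float(gspec.get("g_A_scale", 1.0)))
        log.info("group %s: g_A=%.1f nS", group, g_model.g_A)
        for ci in range(int(cfg["n_cells"])):
            cell_id = f"{group}/cell{ci:02d}"
            culture_id = f"culture{ci % 3}"
            seed = _cell_seed(base_seed, gi, ci)
            rng = np.random.default_rng(seed)
            model = _jitter_model(g_model, float(cfg["param_jitter_cv"]), rng)

            stage = "simulate"
            try:
                traces, gt = simulate_neuron(
                    model, proto, noise_sd=float(cfg["noise_sd_mv"]), seed=seed
                )
                if "features" in analyses:
                    stage = "features"
                    sweeps = [sweep_features(tr, proto) for tr in traces]
                    fic = fi_curve(sweeps)
                    feature_rows.append((cell_id, culture_id, group, "rheobase_pa", fic.rheobase_pa))
                    for cur, rate in zip(fic.currents_pa, fic.rates_hz):
                        fi_rows.append(
                            {"cell_id": cell_id, "group": group,
                             "current": float(cur), "rate": float(rate)}
                        )
                    pp = passive_props(
                        traces[0],
                        pulse_start_ms=proto.epochs[-1].start_ms,
                    )
                    feature_rows += [
                        (cell_id, culture_id, group, "rmp_mv", pp.rmp_mv),
                        (cell_id, culture_id, group, "r_in_mohm", pp.r_in_mohm),
                        (cell_id, culture_id, group, "tau_m_ms", pp.tau_m_ms),
                    ]
                    if not np.isnan(fic.rheobase_pa):
                        idx = list(proto.sweep_levels).index(fic.rheobase_pa)
                        tr = traces[idx]
                        from .spikes import detect_spikes

                        onsets = detect_spikes(tr)
                        if onsets:
                            base_sl = tr.slice_ms(
                                proto.epochs[0].start_ms - 50.0, proto.epochs[0].start_ms
                            )
                            baseline = float(np.mean(tr.signal[base_sl]))
                            feats = ap_features(
                                tr, onsets[0], baseline,
                                next_onset_index=onsets[1] if len(onsets) > 1 else None,
                            )
                            feature_rows += [
                                (cell_id, culture_id, group, "fwhm_ms", feats.fwhm_ms),
                                (cell_id, culture_id, group, "decay_time_37_ms", feats.decay_time_37_ms),
                                (cell_id, culture_id, group, "rise_time_20_80_ms", feats.rise_time_20_80_ms),
                                (cell_id, culture_id, group, "threshold_mv", feats.threshold_v),
                                (cell_id, culture_id, group, "amplitude_mv", feats.amplitude),
                                (cell_id, culture_id, group, "post_spike_voltage_mv", feats.post_spike_voltage),
                            ]
                            if "apcurrent" in analyses:
                                stage = "apcurrent"
                                nc = net_ion_current(tr, model.C, onset_index=onsets[0])
                                feature_rows += [
                                    (cell_id, culture_id, group, "na_peak_pa", nc.na_peak_pa),
                                    (cell_id, culture_id, group, "k_peak_pa", nc.k_peak_pa),
                                ]
                if "ais" in analyses:
                    stage = "ais"
                    a = cfg["ais"]
                    length = float(a["length_um"]) * float(gspec.get("ais_length_scale", 1.0))
                    profile = synth_ais_profile(
                        start_um=float(a["start_um"]),
                        end_um=float(a["start_um"]) + length,
                        edge_sd_um=float(a["edge_sd_um"]),
                        noise_sd=float(a["noise_sd"]),
                        step_um=float(a["step_um"]),
                        seed=seed,
                    )
                    meas = measure_ais(profile)
                    ais_rows.append(
                        {"cell_id": cell_id, "culture_id": culture_id, "group": group,
                         "start_um": meas.start_um, "middle_um": meas.middle_um,
                         "end_um": meas.end_um, "length_um": meas.length_um}
                    )
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage {stage!r} failed for {cell_id}: {exc}"
                ) from exc

        if "vclamp" in analyses:
            # one voltage-clamp isolation per group (TTx vs TTx + 4-AP)
            try:
                vproto = voltage_step_protocol()
                vseed = _cell_seed(base_seed, gi, 999)
                ttx = apply_pharmacology(g_model, "TTx", 1.0)
                dr_only = apply_pharmacology(ttx, "4AP", 1.0)
                tot_tr, _ = simulate_neuron(ttx, vproto, seed=vseed)
                dr_tr, _ = simulate_neuron(dr_only, vproto, seed=vseed + 1)
                diff = subtract_currents(tot_tr, dr_tr)
                iv = measure_iv(diff, statistic="peak", protocol=vproto)
                gv = gv_from_iv(iv, e_rev_mv=g_model.E_K)
                fit = fit_boltzmann(gv)
                vc_fits[group] = {
                    "v_half_mv": fit.v_half_mv,
                    "k_slope_mv": fit.k_slope_mv,
                    "z": fit.z,
                    "gmax_norm": fit.gmax,
                    "iv_voltages_mv": iv.voltages_mv.tolist(),
                    "iv_currents_pa": iv.currents_pa.tolist(),
                }
            except Exception as exc:
                raise RuntimeError(f"pipeline stage 'vclamp' failed for group {group}: {exc}") from exc

    table = make_group_table(feature_rows)
    write_table(table, out / "features.tsv")
    written.append(out / "features.tsv")
    fi_df = pd.DataFrame(fi_rows)
    if len(fi_df):
        write_table(fi_df, out / "fi_curves.tsv")
        written.append(out / "fi_curves.tsv")
    if ais_rows:
        write_table(pd.DataFrame(ais_rows), out / "ais_measures.tsv")
        written.append(out / "ais_measures.tsv")
    if vc_fits:
        p = out / "vclamp_fits.json"
        p.write_text(json.dumps(vc_fits, indent=1, sort_keys=True))
        written.append(p)

    if "stats" in analyses and len(cfg["groups"]) >= 2 and int(cfg["n_cells"]) >= 3:
        rows = []
        for feature in sorted(table["feature"].unique()):
            sub = table.dropna(subset=["value"])
            try:
                rep = compare_groups(sub, feature)
            except ValueError:
                continue
            rows.append(rep.to_row())
        stats_df = pd.DataFrame(rows)
        write_table(stats_df, out / "stats.tsv")
        written.append(out / "stats.tsv")
        if len(fi_df) and fi_df.groupby(["group", "current"]).size().min() >= 2:
            rep = compare_fi(fi_df)
            p = out / "fi_stats.tsv"
            write_table(rep.posthoc.assign(main_p=rep.p_value), p)
            written.append(p)

    manifest = {
        "version": __version__,
        "seed": base_seed,
        "config": cfg,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
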
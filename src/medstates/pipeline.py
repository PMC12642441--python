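"""End-to-end analysis on a synthetic dataset.

``run_pipeline`` generates a seeded dataset with planted effects and runs
every stage: ReHo (raw -> standardized -> smoothed -> parcel means), state
trends with composite-control contrasts, connectivity gradients with
template alignment and G1 dispersion, geometric eigenmode spectra with
state trends, PLSC brain-behavior coupling (after MICE completion),
term-map decoding of delta maps, and the subgroup spatial-similarity
robustness check.  Recovery of the planted effects is scored against the
generators' ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import brain_behavior as bb
from . import decoding as dec
from . import eigenmodes as em
from . import gradients as gr
from . import reho as rh
from . import simulate as sim
from . import trends as tr
from .io import COMPOSITE_CONTROL, STATES


def reho_stage(spec: sim.SimulationSpec, fwhm_mm: float = 2.0,
               cluster_size: int = 27):
    """ReHo maps and parcel means for every participant x condition."""
    images, parc, segments, truth = sim.generate_reho_dataset(spec)
    rows = []
    for (participant, cond), img in images.items():
        raw = rh.compute_reho(img, cluster_size=cluster_size)
        z = rh.zscore_map(raw)
        sm = rh.smooth_map(z, fwhm_mm, img.voxel_size)
        for pid, val in rh.parcel_average(sm, parc).items():
            rows.append({"participant": participant, "condition": cond,
                         "metric": f"parcel_{pid}", "parcel": pid,
                         "value": val})
    return pd.DataFrame(rows), parc, truth


def trend_stage(parcel_table: pd.DataFrame, max_degree: int = 3):
    """Polynomial trends across states plus state-vs-control contrasts."""
    table = tr.composite_control(parcel_table)
    state_rows = table[table["condition"].isin(STATES)].copy()
    state_rows["state"] = state_rows["condition"].map(
        {s: i + 1 for i, s in enumerate(STATES)})
    trend_df = tr.fit_trend_table(state_rows, max_degree=max_degree)
    contrasts = [tr.fit_condition_contrasts(grp, metric=str(m))
                 for m, grp in table.groupby("metric", sort=False)]
    tr.contrasts_across_fdr(contrasts)
    ctrl = [tr.control_vs_control(grp, metric=str(m))
            for m, grp in parcel_table.groupby("metric", sort=False)]
    return trend_df, contrasts, pd.DataFrame(ctrl)


def score_trend_recovery(trend_df: pd.DataFrame, truth: sim.GroundTruth):
    """Fraction of trend-bearing parcels whose leading planted coefficient's
    sign is recovered by the fitted trend of the same degree."""
    hits, total = 0, 0
    for _, row in trend_df.iterrows():
        pid = int(str(row["metric"]).split("_")[-1])
        planted = truth.parcel_trends[pid]
        degree = int(np.argmax(np.abs(planted))) + 1
        coef = planted[degree - 1]
        if coef == 0:
            continue
        total += 1
        recovered = row.get(f"beta{degree}", np.nan)
        if np.isfinite(recovered) and np.sign(recovered) == np.sign(coef):
            hits += 1
    return hits / total if total else float("nan")


def gradient_stage(spec: sim.SimulationSpec, n_components: int = 10,
                   sparsity: float = 0.90):
    """Template gradients, per-segment alignment, and G1 dispersion.

    The headline state/control range ratio uses condition-mean connectivity
    (averaging FC before embedding, as the template step does), which
    suppresses the finite-sample noise that biases per-segment embeddings.
    """
    series, networks, truth = sim.generate_gradient_dataset(spec)
    fc = {key: gr.functional_connectivity(gr.ParcelSeries(data))
          for key, data in series.items()}
    template = gr.compute_template(list(fc.values()), n_components, sparsity)
    rows = []
    for (participant, cond), R in fc.items():
        g = gr.diffusion_map_embed(
            gr.cosine_affinity(gr.sparsify(R, sparsity)), n_components)
        aligned = gr.procrustes_align(g, template)
        rng_, sd = gr.gradient_dispersion(aligned, 1)
        rows.append({"participant": participant, "condition": cond,
                     "g1_range": rng_, "g1_sd": sd})

    def condition_mean_range(conditions) -> float:
        mats = [R for (p, c), R in fc.items() if c in conditions]
        g = gr.diffusion_map_embed(
            gr.cosine_affinity(gr.sparsify(np.mean(mats, axis=0), sparsity)),
            n_components)
        return gr.gradient_dispersion(gr.procrustes_align(g, template), 1)[0]

    ratio = (condition_mean_range(spec.states)
             / condition_mean_range(spec.controls))
    return pd.DataFrame(rows), template, truth, ratio


def eigenmode_stage(spec: sim.SimulationSpec, subdivisions: int = 3,
                    n_modes: int = 40, n_signal_modes: int = 9):
    """Eigenmode basis, per-state spectra, and the planted log-power trend."""
    mesh = sim.generate_mesh("icosphere", subdivisions)
    A, M = em.assemble_lbo(mesh.vertices, mesh.faces)
    basis = em.solve_eigenmodes(A, M, n_modes)
    amps = np.asarray(spec.mode_amplitudes, dtype=float)
    schedule = np.zeros((n_signal_modes + 1, len(spec.states)))
    schedule[1:] = amps  # mode 1 (constant) silent; modes 2..n carry the shape
    rows = []
    for p in range(spec.n_participants):
        child = int(np.random.SeedSequence(
            entropy=spec.seed, spawn_key=(701, p)).generate_state(1)[0] % 2**31)
        data, _ = sim.generate_mode_timeseries(
            basis, schedule, noise_sd=0.1, seed=child,
            t_per_segment=spec.t_per_segment, states=spec.states)
        for s_idx, state in enumerate(spec.states):
            spect = em.spectra(em.project_timeseries(data[state], basis), basis)
            summ = em.segment_summary(spect)
            rows.append({"participant": f"sub{p + 1:02d}", "condition": state,
                         "state": s_idx + 1,
                         "mean_power": float(summ["mean_power"][1:n_signal_modes + 1].mean()),
                         "mean_energy": float(summ["mean_energy"][1:n_signal_modes + 1].mean()),
                         "total_power": summ["total_power"],
                         "total_energy": summ["total_energy"]})
    df = pd.DataFrame(rows)
    long = df.rename(columns={"mean_power": "value"})[
        ["participant", "state", "value"]]
    trend = tr.fit_trend_lmm(long.assign(state=long["state"]),
                             max_degree=3, metric="mean_power")
    return df, trend


def behavior_stage(spec: sim.SimulationSpec, parcel_table: pd.DataFrame,
                   n_perm: int = 1000, n_boot: int = 500):
    """MICE completion and PLSC per behavioral domain."""
    wide = (parcel_table[parcel_table["condition"].isin(STATES)]
            .pivot_table(index=["participant", "condition"], columns="metric",
                         values="value").reset_index())
    keys = wide[["participant", "condition"]]
    X = wide.drop(columns=["participant", "condition"]).to_numpy(float)
    tables, truth = sim.generate_behavior_tables(spec, X, row_keys=keys)
    results = {}
    for domain, tab in tables.items():
        Y = tab.drop(columns=["participant", "condition"])
        Y = bb.mice_impute(Y, seed=spec.seed).to_numpy(float)
        fit = bb.plsc_fit(X, Y)
        bb.plsc_permutation(X, Y, fit, n_perm=n_perm, seed=spec.seed)
        bb.plsc_bootstrap(X, Y, fit, n_boot=n_boot, seed=spec.seed)
        results[domain] = fit
    return results, truth


def decoding_stage(parcel_table: pd.DataFrame, n_terms: int = 123,
                   r_target: float = 0.9, seed: int = 0, top_k: int = 10):
    """Delta maps vs composite control, decoded against a planted library."""
    means = (parcel_table.groupby(["condition", "metric"], sort=False)["value"]
             .mean().unstack("metric"))
    control = means.loc[["counting", "memory"]].mean(axis=0).to_numpy()
    deltas = {s: dec.delta_map(means.loc[s].to_numpy(), control)
              for s in STATES if s in means.index}
    target = deltas["J8"]
    library, truth = sim.generate_term_library(
        n_terms, target.size, planted=("planted_term", target, r_target),
        seed=seed)
    decoded = {s: dec.correlation_decode(d, library, top_k=top_k)
               for s, d in deltas.items()}
    return decoded, library, truth


def robustness_stage(parcel_table: pd.DataFrame, n_perm: int = 2000,
                     seed: int = 0):
    """Split-half subgroup spatial similarity per state plus its trend."""
    participants = sorted(parcel_table["participant"].unique())
    half = len(participants) // 2
    ga, gb = set(participants[:half]), set(participants[half:])
    states = [s for s in STATES if s in set(parcel_table["condition"])]

    def group_maps(group):
        sub = parcel_table[parcel_table["participant"].isin(group)]
        m = (sub[sub["condition"].isin(states)]
             .groupby(["condition", "metric"], sort=False)["value"].mean()
             .unstack("metric"))
        return {s: m.loc[s].to_numpy() for s in states}

    sims = dec.subgroup_similarity(group_maps(ga), group_maps(gb),
                                   n_perm=n_perm, seed=seed)
    trend = dec.similarity_trend({s: sims[s]["r"] for s in sims})
    return sims, trend


def run_pipeline(spec: sim.SimulationSpec | None = None, seed: int = 0,
                 n_perm: int = 1000, n_boot: int = 500) -> dict:
    """Run every stage on one synthetic dataset and score planted-effect recovery."""
    if spec is None:
        spec = sim.SimulationSpec(
            seed=seed,
            gradient_compression={s: 0.5 for s in STATES})
    parcel_table, parc, reho_truth = reho_stage(spec)
    trend_df, contrasts, ctrl = trend_stage(parcel_table)
    sign_recovery = score_trend_recovery(trend_df, reho_truth)

    grad_df, template, grad_truth, g1_ratio = gradient_stage(spec)

    em_df, em_trend = eigenmode_stage(spec)
    plsc_results, behavior_truth = behavior_stage(spec, parcel_table,
                                                  n_perm=n_perm, n_boot=n_boot)
    decoded, library, dec_truth = decoding_stage(parcel_table, seed=spec.seed)
    sims, sim_trend = robustness_stage(parcel_table, seed=spec.seed)

    return {
        "parcel_table": parcel_table,
        "trends": trend_df,
        "contrasts": contrasts,
        "control_vs_control": ctrl,
        "trend_sign_recovery": sign_recovery,
        "gradient_dispersion": grad_df,
        "g1_range_ratio": float(g1_ratio),
        "eigenmode_summaries": em_df,
        "eigenmode_trend": em_trend,
        "plsc": plsc_results,
        "decoding": decoded,
        "subgroup_similarity": sims,
        "similarity_trend": sim_trend,
        "truth": {"reho": reho_truth, "gradients": grad_truth,
                  "behavior": behavior_truth, "decoding": dec_truth},
    }
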
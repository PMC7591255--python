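"""End-to-end validation experiments on synthetic data.

Each function runs one self-contained study -- generate data with known
ground truth, run the corresponding estimator, and measure how well the
truth is recovered -- or exercises the shipped SSN calibration and reports
the qualitative circuit phenomenology.  They are used both by the test
suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import crf, glm, ssn, synth, tuning


def chisq_type1_rate(
    n_cells: int = 2000,
    n_reps: int = 15,
    n_shuffles: int = 2000,
    alpha: float = 0.01,
    seed: int = 0,
) -> dict:
    """Fraction of exchangeable null cells called responsive at ``alpha``.

    Flat-preset cells have no stimulus, direction or locomotion dependence,
    so the bootstrapped chi-square test should fire at ~``alpha``.
    """
    rng = np.random.default_rng(seed)
    stim = synth.make_stimulus_table(n_reps=n_reps, n_blanks=30, seed=rng)
    truth = synth.sample_population_tuning({"flat": 1.0}, n_cells, seed=rng)
    responses = synth.generate_event_responses(stim, truth, seed=rng)
    _, p = tuning.chisq_responsiveness_batch(
        responses, stim, n_shuffles=n_shuffles, seed=rng
    )
    half_width = 1.96 * np.sqrt(alpha * (1 - alpha) / n_cells)
    return {
        "rate": float((p < alpha).mean()),
        "n_cells": n_cells,
        "interval": (alpha - half_width, alpha + half_width),
    }


def metric_closed_forms() -> dict:
    """Exemplar values of gOSI, DSI and cCoM with known closed forms."""
    single_dir = np.zeros(8)
    single_dir[2] = 1.0
    opposite = np.zeros(8)
    opposite[[0, 4]] = 1.0
    single_con = np.zeros(6)
    single_con[3] = 2.0
    extremes = np.zeros(6)
    extremes[[0, 5]] = 1.0
    cases = [
        ("gosi_single_direction", tuning.gosi(single_dir), 1.0),
        ("gosi_uniform", tuning.gosi(np.ones(8)), 0.0),
        ("gosi_opposite_doubled", tuning.gosi(opposite), 1.0),
        ("gosi_opposite_literal", tuning.gosi(opposite, convention="literal"), 0.0),
        ("dsi_2_vs_1", tuning.dsi(2.0, 1.0), 1.0 / 3.0),
        ("dsi_null_zero", tuning.dsi(1.0, 0.0), 1.0),
        ("dsi_equal", tuning.dsi(1.0, 1.0), 0.0),
        ("ccom_single_40pct", tuning.contrast_com(single_con), 0.40),
        ("ccom_extremes", tuning.contrast_com(extremes), 0.20),
        ("rn_example", tuning.normalized_response(3.0, 1.0, 2.0), 2.0 / 3.0),
    ]
    return {
        "cases": {name: value for name, value, _ in cases},
        "max_abs_error": float(
            max(abs(value - expected) for _, value, expected in cases)
        ),
        "n_cases": len(cases),
    }


def crf_class_recovery(
    n_cells_per_class: int = 100,
    n_reps: int = 15,
    gamma_shape: float = 16.0,
    seed: int = 0,
) -> dict:
    """Correct-classification rate per contrast-response class.

    High-SNR cells (low-CV gamma noise, no zero inflation) are drawn from
    the generator's class-parameter distributions at the preferred
    direction and classified with the normal-likelihood AIC comparison (the
    shuffle likelihood saturates for well-fitting models and cannot select
    the 4-parameter band-pass model; see the tuning methods note).
    """
    rng = np.random.default_rng(seed)
    contrasts = np.repeat(synth.CONTRASTS, n_reps)
    out = {}
    for cls in ("low_pass", "high_pass", "band_pass"):
        hits = 0
        for _ in range(n_cells_per_class):
            params = synth._sample_class_params(cls, rng)
            mu = 0.1 * synth.contrast_kernel(
                {"contrast_class": cls, **params}, contrasts
            )
            y = rng.gamma(gamma_shape, 1.0, mu.shape) * mu / gamma_shape
            sel = crf.select_contrast_model(
                contrasts, y, seed=rng, likelihood="normal"
            )
            hits += sel.kind == cls
        out[cls] = 100.0 * hits / n_cells_per_class
    out["n_cells_per_class"] = n_cells_per_class
    return out


def glm_sign_recovery(
    n_sessions: int = 3,
    n_planted: int = 12,
    noise_scale: float = 0.1,
    seed: int = 0,
) -> dict:
    """Sign agreement of planted sparse GLM weights at the CV-chosen penalty.

    Twelve terms get nonzero weights; trial responses are sampled with
    Poisson-like (variance proportional to mean) gamma noise, the penalty is
    chosen by leave-one-session-out cross validation, and agreement is the
    fraction of planted terms whose fitted sign matches (a zeroed-out weight
    counts as disagreement).
    """
    rng = np.random.default_rng(seed)
    stim = synth.make_stimulus_table(
        n_reps=15, n_blanks=30, n_sessions=n_sessions, seed=rng
    )
    X, _ = glm.build_design_matrix(stim)
    idx = rng.choice(30, size=n_planted, replace=False)  # main effects + low dxc
    w = np.zeros(glm.N_TERMS)
    w[idx] = rng.uniform(0.4, 1.0, n_planted) * rng.choice([1.0, -1.0], n_planted)
    mu = np.exp(X @ w + np.log(0.5))
    y = rng.gamma(mu / noise_scale, noise_scale)
    lam, _ = glm.cross_validate_lambda(X, y, stim["session_id"].to_numpy())
    fit = glm.fit_l1(X, y, lam)
    agreement = float((np.sign(fit.w[idx]) == np.sign(w[idx])).mean())
    return {
        "sign_agreement_pct": 100.0 * agreement,
        "lam": lam,
        "n_planted": n_planted,
    }


def stability_oracle_agreement(
    n_e_ring: int = 60, strengths: np.ndarray | None = None
) -> dict:
    """Analytic E-E stability sign vs a finite-difference Jacobian oracle.

    On a reduced homogeneous ring (uniform external drive, no 0-degree input
    bias) the Fourier-domain analysis is exact, so the sign of
    ``J00 - 1`` must match the sign of the leading eigenvalue of the
    numerically differentiated E-E Jacobian sub-block at every drive
    strength.
    """
    if strengths is None:
        strengths = np.arange(0.0, 19.0, 2.0)  # spans the non-ISN -> ISN crossing
    cfg = ssn.NetworkConfig(
        n_e_ring=n_e_ring, n_e_extra=0, n_pv=1, n_sst=1, n_vip=1, input_bias=0.0
    )
    net = ssn.SSNetwork(cfg)
    e_sl = net.slices["e"]
    idx = np.arange(e_sl.start, e_sl.stop)
    matches = 0
    signs = []
    r0 = None
    for s in strengths:
        state = ssn.steady_state(net, net.external_drive(float(s), direction=None), r0=r0)
        if not state.steady:
            signs.append(None)
            continue
        r0 = state.r
        analytic = ssn.ee_stability(net, state).ee_stability

        def f(rvec):
            I = net.i_sp + state.drive + net.W @ rvec
            return net.rate_transfer(I) - rvec

        eps = 1e-6
        f0 = f(state.r)
        J = np.empty((idx.size, idx.size))
        for col, i in enumerate(idx):
            rp = state.r.copy()
            rp[i] += eps
            J[:, col] = (f(rp)[idx] - f0[idx]) / eps
        lead = float(np.max(np.real(np.linalg.eigvals(J))))
        matches += np.sign(analytic) == np.sign(lead)
        signs.append((float(analytic), lead))
    return {
        "agreement_pct": 100.0 * matches / len(strengths),
        "n_strengths": int(len(strengths)),
        "details": signs,
    }


def ssn_qualitative_suite(
    strengths: np.ndarray | None = None,
    gain_spacing: float = 2.0,
    pv_fractions: tuple = (0.2, 0.35, 0.5, 0.65, 0.8, 0.9, 0.97),
) -> dict:
    """Phenomenology of the shipped calibration on the full-size network.

    Measures: VIP suppression at maximal drive, the single non-ISN -> ISN
    transition, the low-drive-only gain enhancement from the VIP->SST
    connection, the critical VIP->SST magnitude and the above-critical
    instability with silenced SST, and the PV-fraction stability range.
    """
    if strengths is None:
        strengths = np.arange(0.0, 101.0, 10.0)
    cfg = ssn.NetworkConfig()
    net = ssn.SSNetwork(cfg)
    out: dict = {"n_units": net.n, "n_e": cfg.n_e}

    # stability along the drive axis
    stab = ssn.stability_curve(net, strengths)
    ee = stab["ee_stability"].to_numpy()
    crossings = np.flatnonzero(np.diff((ee > 0).astype(int)))
    out["isn_sign_changes"] = int(len(crossings))
    out["isn_transition_strength"] = (
        float(strengths[crossings[0] + 1]) if len(crossings) else float("nan")
    )
    out["all_steady_at_default"] = bool((stab["regime"] != "unstable").all())

    # VIP suppression below spontaneous at maximal drive
    r0 = None
    vip_rates = {}
    for s in (0.0, float(strengths[-1])):
        state = ssn.steady_state(net, net.external_drive(s, 0.0))
        vip_rates[s] = state.pop_rates(net)["vip"]
    out["vip_rate_zero_drive"] = vip_rates[0.0]
    out["vip_rate_max_drive"] = vip_rates[float(strengths[-1])]

    # delta gain: intact minus VIP->SST-ablated
    gain_grid = np.arange(0.0, strengths[-1] + 1e-9, gain_spacing)
    intact, ablated, dg = ssn.delta_gain(cfg, gain_grid)
    finite = np.isfinite(dg)
    out["delta_gain_max"] = float(np.max(dg[finite]))
    out["delta_gain_max_strength"] = float(gain_grid[finite][np.argmax(dg[finite])])
    high = finite & (gain_grid > 0.6 * strengths[-1])
    out["delta_gain_high_drive_max"] = float(np.max(dg[high]))
    sst = intact.pop_rates.query("pop == 'sst'")["rate_at_zero_deg"].to_numpy()
    out["sst_peak_strength"] = float(gain_grid[int(np.nanargmax(sst))])

    # critical VIP->SST coupling and the stated operating point
    crit = ssn.find_critical_vip_sst(cfg, strengths, lo=0.5, hi=0.7, tol=0.003)
    out["critical_vip_sst"] = float(crit)
    out["w_over_w_critical"] = float(abs(cfg.couplings.vip_sst) / crit)

    # above critical: instability with silenced SST
    sweep = ssn.sweep_parameter(
        cfg, "w_vip_sst", [-1.25 * crit], np.arange(0.0, 41.0, 10.0)
    )
    out["above_critical_unstable_points"] = int((sweep["regime"] == "unstable").sum())
    steady = sweep[sweep["regime"] != "unstable"]
    out["above_critical_max_sst_rate"] = float(steady["rate_sst"].max())

    # PV-fraction sweep
    sweep2 = ssn.sweep_parameter(cfg, "pv_fraction", list(pv_fractions), strengths)
    fully_stable = [
        float(v)
        for v, g in sweep2.groupby("value")
        if (g["regime"] != "unstable").all()
    ]
    out["pv_fraction_stable_min"] = min(fully_stable) if fully_stable else float("nan")
    out["pv_fraction_stable_max"] = max(fully_stable) if fully_stable else float("nan")
    unstable = sorted(
        float(v)
        for v, g in sweep2.groupby("value")
        if (g["regime"] == "unstable").any()
    )
    out["pv_fraction_first_unstable"] = unstable[0] if unstable else float("nan")
    return out
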
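"""MCMC fitting of the hierarchical mixture model.

The sampler is a blocked Gibbs scheme tailored to the model's structure:

* **Component assignments** of individual records are drawn from their
  categorical conditionals (mixture data augmentation), which makes every
  location parameter conditionally Gaussian.
* **All location parameters** (global/region/country intercepts and slopes,
  the three levels of random-walk trend increments, covariate coefficients,
  and per-survey non-sampling effects) are drawn jointly from their exact
  multivariate-normal conditional by Cholesky factorisation of the full
  conditional precision.  Reported prevalences, which enter the likelihood
  nonlinearly, are folded in through a Metropolis accept/reject of this
  joint proposal, so the chain still targets the full posterior.
* **Pregnancy offsets** are drawn country-by-country from truncated-normal
  conditionals (again Metropolis-corrected for prevalence terms).
* **Mixture shape** (ordered offsets, weights, component sds) moves by
  adaptive random-walk Metropolis; weights use a Dirichlet proposal.
* **Variance hyperparameters** move by univariate slice sampling on the log
  scale.

Retained-draw count is exactly ``target_retained`` pooled across chains, and
the whole fit is deterministic given (data, configs, seed).
"""

from __future__ import annotations

import json
import math
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.stats import truncnorm

from .groups import FAMILY_WOMEN
from .model import (
    FamilyModelData,
    FamilyParameters,
    G_COMBINED,
    G_MAIN,
    G_PREGNANT,
    HYPER_NAMES,
    ModelConfig,
    _design_var,
    _norm_logpdf,
    logposterior,
    rw2_logpdf,
)


@dataclass(frozen=True)
class FitConfig:
    """Chain setup; ``target_retained`` draws are pooled across chains."""

    chains: int = 4
    warmup: int = 1000
    target_retained: int = 2500
    seed: int = 0
    thin: int = 1

    def __post_init__(self) -> None:
        if min(self.chains, self.warmup, self.target_retained, self.thin) < 1:
            raise ValueError("chains, warmup, target_retained, thin must be positive")

    @property
    def per_chain(self) -> int:
        return -(-self.target_retained // self.chains)  # ceil


# --------------------------------------------------------------------------
# slice sampler (univariate, stepping-out + shrinkage)
# --------------------------------------------------------------------------


def _slice_sample(logf, x0: float, rng: np.random.Generator, w: float = 1.0, max_steps: int = 50) -> float:
    y0 = logf(x0) - rng.exponential()
    u = rng.random()
    lo, hi = x0 - w * u, x0 + w * (1.0 - u)
    for _ in range(max_steps):
        if logf(lo) <= y0:
            break
        lo -= w
    for _ in range(max_steps):
        if logf(hi) <= y0:
            break
        hi += w
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logf(x1) >= y0:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # numerical corner: keep the current value


# --------------------------------------------------------------------------
# per-family sampler
# --------------------------------------------------------------------------


class _Layout:
    """Index layout of the jointly-Gaussian location block."""

    def __init__(self, data: FamilyModelData):
        i = 0

        def take(n):
            nonlocal i
            s = slice(i, i + n)
            i += n
            return s

        C, R, T, P, S = data.C, data.R, data.T, data.P, data.n_ind_surveys
        self.a0 = take(1)
        self.b0 = take(1)
        self.ar = take(R)
        self.br = take(R)
        self.ac = take(C)
        self.bc = take(C)
        self.u0 = take(T)
        self.ur = take(R * T)
        self.uc = take(C * T)
        self.beta = take(P)
        self.e = take(S)
        self.dim = i


class _FamilySampler:
    def __init__(self, data: FamilyModelData, cfg: ModelConfig, rng: np.random.Generator):
        self.data = data
        self.cfg = cfg
        self.rng = rng
        self.lay = _Layout(data)
        self.K = cfg.n_components
        self.is_women = data.family == FAMILY_WOMEN
        self._build_design()
        self._init_params()
        self.accept = {"location": [0, 0], "delta": [0, 0], "offsets": [0, 0], "weights": [0, 0], "taus": [0, 0]}
        self.step = {"offsets": 0.5, "weights": 400.0, "taus": 0.05}
        self._adapting = True

    # ---- design matrices -------------------------------------------------
    def _row_pattern(self, ci: int, ti: int, year: float):
        d, lay = self.data, self.lay
        ri = int(d.region_idx[ci])
        row = np.zeros(lay.dim)
        t = year - d.t_ref
        row[lay.a0] = 1.0
        row[lay.b0] = t
        row[lay.ar.start + ri] = 1.0
        row[lay.br.start + ri] = t
        row[lay.ac.start + ci] = 1.0
        row[lay.bc.start + ci] = t
        row[lay.u0.start + ti] = 1.0
        row[lay.ur.start + ri * d.T + ti] = 1.0
        row[lay.uc.start + ci * d.T + ti] = 1.0
        row[lay.beta] = d.X[ci, ti]
        return row

    def _build_design(self) -> None:
        d = self.data
        # summary rows carrying a mean
        self.sm_idx = np.where(~np.isnan(d.s_mean))[0]
        rows = [self._row_pattern(d.s_country[i], d.s_tidx[i], d.s_year[i]) for i in self.sm_idx]
        self.sm_cdelta = np.array(
            [
                -1.0 if d.s_gcode[i] == G_PREGNANT else (-d.s_pregfrac[i] if d.s_gcode[i] == G_COMBINED else 0.0)
                for i in self.sm_idx
            ]
        )
        self.sm_country = d.s_country[self.sm_idx]
        self.sm_y = d.s_mean[self.sm_idx]
        # pseudo-rows: one per (individual cell x mixture component)
        cell_rows = []
        for j in range(d.n_cells):
            r = self._row_pattern(int(d.cell_country[j]), int(d.cell_tidx[j]), float(d.cell_year[j]))
            r[self.lay.e.start + int(d.cell_survey[j])] = 1.0
            cell_rows.append(r)
        self.cell_cdelta = np.where(d.cell_gcode == G_PREGNANT, -1.0, 0.0)
        ps_rows = [cell_rows[j] for j in range(d.n_cells) for _ in range(self.K)]
        self.ps_cell = np.repeat(np.arange(d.n_cells), self.K)
        self.ps_comp = np.tile(np.arange(self.K), d.n_cells)
        self.A = np.array(rows + ps_rows) if (rows or ps_rows) else np.zeros((0, self.lay.dim))
        self.n_sm = len(self.sm_idx)
        # per-record sums for the pseudo-rows (filled each iteration)
        mode = self.cfg.prevalence_mode
        qual = (~np.isnan(d.s_prev)) | (~np.isnan(d.s_prevsev))
        if mode == "when_mean_absent":
            qual &= np.isnan(d.s_mean)
        self.has_prev = mode != "never" and bool(qual.any())

    # ---- initialisation --------------------------------------------------
    def _init_params(self) -> None:
        d, cfg, rng = self.data, self.cfg, self.rng
        means = [m for m in d.s_mean if not np.isnan(m)]
        if d.rec_hb.size:
            means.append(float(d.rec_hb.mean()))
        self.a0_loc = float(np.mean(means)) if means else 120.0
        pooled_sd = float(d.rec_hb.std()) if d.rec_hb.size > 10 else 12.0
        jit = lambda s: rng.normal(0.0, s)
        K = self.K
        base_off = np.linspace(-2.0, 1.6, K) * max(pooled_sd, 6.0) * 0.9
        hypers = {
            "sd_ar": cfg.region_intercept_scale * 0.4,
            "sd_br": cfg.region_slope_scale * 0.3,
            "sd_ac": cfg.country_intercept_scale * 0.4,
            "sd_bc": cfg.country_slope_scale * 0.3,
            "sd_u0": cfg.rw2_scale_global * 0.5,
            "sd_ur": cfg.rw2_scale_region * 0.5,
            "sd_uc": cfg.rw2_scale_country * 0.5,
            "sigma_ns": 2.0,
            "sigma_sub": 2.0,
            "sigma_age": 1.5,
            "sigma_delta": 2.0,
        }
        self.params = FamilyParameters(
            a0=self.a0_loc + jit(1.0),
            b0=jit(0.02),
            ar=np.zeros(d.R),
            br=np.zeros(d.R),
            ac=np.zeros(d.C),
            bc=np.zeros(d.C),
            u0=np.zeros(d.T),
            ur=np.zeros((d.R, d.T)),
            uc=np.zeros((d.C, d.T)),
            beta=np.zeros(d.P),
            e=np.zeros(d.n_ind_surveys),
            offsets_raw=np.sort(base_off + rng.normal(0, 0.1, K)),
            weights=np.array([0.1, 0.2, 0.4, 0.2, 0.1])[:K] / np.sum(np.array([0.1, 0.2, 0.4, 0.2, 0.1])[:K]),
            taus=np.full(K, max(pooled_sd, 6.0) * 0.8) * np.linspace(1.1, 0.85, K),
            hypers=hypers,
            delta=(np.full(d.C, cfg.delta_mu0_loc) + rng.normal(0, 0.3, d.C)).clip(0.1) if self.is_women else None,
            mu_delta_region=np.full(d.R, cfg.delta_mu0_loc) if self.is_women else None,
            mu_delta0=cfg.delta_mu0_loc if self.is_women else None,
        )
        self.z = np.zeros(len(d.rec_hb), dtype=int)
        lp = logposterior(self.params, d, cfg, a0_loc=self.a0_loc)
        if not math.isfinite(lp):
            raise RuntimeError(
                f"non-finite log posterior at initialisation for family {d.family!r}; "
                "check mixture shape and variance starting values"
            )

    # ---- conditional pieces ----------------------------------------------
    def _prev_ll(self, params: FamilyParameters) -> float:
        if not self.has_prev:
            return 0.0
        from .model import prevalence_loglik_from_stats, prevalence_model_stats

        stats = prevalence_model_stats(params, self.data, mode=self.cfg.prevalence_mode)
        dvar = _design_var(params, self.data.s_sub, self.data.s_agemis)
        return prevalence_loglik_from_stats(self.data, stats, dvar, self.cfg.prev_floor)

    def _x_from_params(self) -> np.ndarray:
        p, lay = self.params, self.lay
        x = np.empty(lay.dim)
        x[lay.a0] = p.a0
        x[lay.b0] = p.b0
        x[lay.ar] = p.ar
        x[lay.br] = p.br
        x[lay.ac] = p.ac
        x[lay.bc] = p.bc
        x[lay.u0] = p.u0
        x[lay.ur] = p.ur.ravel()
        x[lay.uc] = p.uc.ravel()
        x[lay.beta] = p.beta
        x[lay.e] = p.e
        return x

    def _params_from_x(self, x: np.ndarray, into: FamilyParameters) -> None:
        lay, d = self.lay, self.data
        into.a0 = float(x[lay.a0][0])
        into.b0 = float(x[lay.b0][0])
        into.ar = x[lay.ar].copy()
        into.br = x[lay.br].copy()
        into.ac = x[lay.ac].copy()
        into.bc = x[lay.bc].copy()
        into.u0 = x[lay.u0].copy()
        into.ur = x[lay.ur].reshape(d.R, d.T).copy()
        into.uc = x[lay.uc].reshape(d.C, d.T).copy()
        into.beta = x[lay.beta].copy()
        into.e = x[lay.e].copy()

    def _record_base(self) -> np.ndarray:
        """Location (incl. survey effect and pregnancy offset) per record."""
        d, p = self.data, self.params
        from .model import theta_grid

        th = theta_grid(p, d)
        base = th[d.cell_country, d.cell_tidx] + p.e[d.cell_survey]
        if p.delta is not None:
            base = base - np.where(d.cell_gcode == G_PREGNANT, p.delta[d.cell_country], 0.0)
        return base[d.rec_cell]

    # ---- updates ----------------------------------------------------------
    def _update_z(self) -> None:
        d = self.data
        if not d.rec_hb.size:
            return
        p = self.params
        resid = d.rec_hb - self._record_base()
        logp = np.log(p.weights)[None, :] + _norm_logpdf(
            resid[:, None], p.offsets[None, :], p.taus[None, :]
        )
        g = self.rng.gumbel(size=logp.shape)
        self.z = np.argmax(logp + g, axis=1)

    def _pseudo_stats(self):
        """Counts and mean residual sums per (cell, component)."""
        d = self.data
        idx = self.z + self.K * d.rec_cell
        n = np.bincount(idx, minlength=d.n_cells * self.K).astype(float)
        s = np.bincount(idx, weights=d.rec_hb, minlength=d.n_cells * self.K)
        return n, s

    def _update_location(self) -> None:
        d, cfg, lay, p = self.data, self.cfg, self.lay, self.params
        h = p.hypers
        Q = np.zeros((lay.dim, lay.dim))
        b = np.zeros(lay.dim)
        # prior precision
        Q[lay.a0.start, lay.a0.start] = 1.0 / cfg.a0_scale**2
        b[lay.a0.start] = self.a0_loc / cfg.a0_scale**2
        Q[lay.b0.start, lay.b0.start] = 1.0 / cfg.b0_scale**2
        for sl, sd in ((lay.ar, h["sd_ar"]), (lay.br, h["sd_br"]), (lay.ac, h["sd_ac"]), (lay.bc, h["sd_bc"])):
            Q[np.arange(sl.start, sl.stop), np.arange(sl.start, sl.stop)] = 1.0 / sd**2
        T = d.T
        if not hasattr(self, "_K2"):
            D2 = np.zeros((T - 2, T))
            for i in range(T - 2):
                D2[i, i : i + 3] = (1.0, -2.0, 1.0)
            self._K2 = D2.T @ D2
            tg = np.arange(T, dtype=float)
            tcn = (tg - tg.mean()) / math.sqrt(float(((tg - tg.mean()) ** 2).sum()))
            ones = np.full(T, 1.0 / T)
            self._KC = np.outer(ones, ones) + np.outer(tcn, tcn)
        eps2 = cfg.rw2_constraint_sd**2
        for sl, sd, count in ((lay.u0, h["sd_u0"], 1), (lay.ur, h["sd_ur"], d.R), (lay.uc, h["sd_uc"], d.C)):
            Qu = self._K2 / sd**2 + self._KC / eps2
            for j in range(count):
                s0 = sl.start + j * T
                Q[s0 : s0 + T, s0 : s0 + T] += Qu
        for j in range(lay.beta.start, lay.beta.stop):
            Q[j, j] += 1.0 / cfg.beta_scale**2
        if d.n_ind_surveys:
            evar = _design_var(p, d.isurv_sub, d.isurv_agemis)
            Q[np.arange(lay.e.start, lay.e.stop), np.arange(lay.e.start, lay.e.stop)] += 1.0 / evar

        # observation contributions
        if self.A.shape[0]:
            w = np.empty(self.A.shape[0])
            y = np.empty(self.A.shape[0])
            if self.n_sm:
                dvar = _design_var(p, d.s_sub[self.sm_idx], d.s_agemis[self.sm_idx])
                w[: self.n_sm] = 1.0 / (d.s_sd[self.sm_idx] ** 2 / d.s_n[self.sm_idx] + dvar)
                fold = 0.0 if p.delta is None else self.sm_cdelta * p.delta[self.sm_country]
                y[: self.n_sm] = self.sm_y - fold
            if d.n_cells:
                n_ck, s_ck = self._pseudo_stats()
                taus = p.taus[self.ps_comp]
                w[self.n_sm :] = n_ck / taus**2
                with np.errstate(invalid="ignore", divide="ignore"):
                    ybar = np.where(n_ck > 0, s_ck / np.where(n_ck > 0, n_ck, 1.0), 0.0)
                fold_c = 0.0 if p.delta is None else self.cell_cdelta[self.ps_cell] * p.delta[d.cell_country[self.ps_cell]]
                y[self.n_sm :] = ybar - p.offsets[self.ps_comp] - fold_c
            Aw = self.A * w[:, None]
            Q += Aw.T @ self.A
            b += Aw.T @ y

        try:
            cf = cho_factor(Q, lower=True)
        except np.linalg.LinAlgError:
            Q = Q + (1e-10 * np.abs(np.diag(Q)).max() + 1e-8) * np.eye(lay.dim)
            cf = cho_factor(Q, lower=True)
        mean = cho_solve(cf, b)
        zvec = self.rng.standard_normal(lay.dim)
        x_new = mean + solve_triangular(cf[0].T, zvec, lower=False)

        self.accept["location"][1] += 1
        if self.has_prev:
            cand = self.params.copy()
            self._params_from_x(x_new, cand)
            logr = self._prev_ll(cand) - self._prev_ll(self.params)
            if math.log(self.rng.random() + 1e-300) < logr:
                self.params = cand
                self.accept["location"][0] += 1
        else:
            self._params_from_x(x_new, self.params)
            self.accept["location"][0] += 1

    def _update_delta(self) -> None:
        if not self.is_women:
            return
        d, p = self.data, self.params
        h = p.hypers
        x = self._x_from_params()
        prior_prec = 1.0 / h["sigma_delta"] ** 2
        mu_r = p.mu_delta_region[d.region_idx]
        prec = np.full(d.C, prior_prec)
        num = mu_r * prior_prec
        if self.n_sm:
            dvar = _design_var(p, d.s_sub[self.sm_idx], d.s_agemis[self.sm_idx])
            w = 1.0 / (d.s_sd[self.sm_idx] ** 2 / d.s_n[self.sm_idx] + dvar)
            r = self.sm_y - self.A[: self.n_sm] @ x
            c = self.sm_cdelta
            np.add.at(prec, self.sm_country, c * c * w)
            np.add.at(num, self.sm_country, c * w * r)
        if d.n_cells:
            n_ck, s_ck = self._pseudo_stats()
            taus = p.taus[self.ps_comp]
            w = n_ck / taus**2
            with np.errstate(invalid="ignore", divide="ignore"):
                ybar = np.where(n_ck > 0, s_ck / np.where(n_ck > 0, n_ck, 1.0), 0.0)
            yr = ybar - p.offsets[self.ps_comp]
            r = yr - self.A[self.n_sm :] @ x
            c = self.cell_cdelta[self.ps_cell]
            cc = d.cell_country[self.ps_cell]
            np.add.at(prec, cc, c * c * w)
            np.add.at(num, cc, c * w * r)
        m = num / prec
        sd = 1.0 / np.sqrt(prec)
        a = (0.0 - m) / sd
        prop = truncnorm.ppf(self.rng.random(d.C), a, np.inf) * sd + m
        self.accept["delta"][1] += 1
        if self.has_prev:
            cand = self.params.copy()
            cand.delta = prop
            logr = self._prev_ll(cand) - self._prev_ll(self.params)
            if math.log(self.rng.random() + 1e-300) < logr:
                self.params = cand
                self.accept["delta"][0] += 1
        else:
            p.delta = prop
            self.accept["delta"][0] += 1

    # mixture shape -------------------------------------------------------
    def _shape_ll(self, params: FamilyParameters) -> float:
        d, cfg = self.data, self.cfg
        ll = 0.0
        if d.rec_hb.size:
            resid = d.rec_hb - self._record_base_for(params)
            o = params.offsets
            ll += float(
                np.sum(
                    np.log(params.weights[self.z])
                    + _norm_logpdf(resid - o[self.z], 0.0, params.taus[self.z])
                )
            )
        ll += self._prev_ll(params)
        # shape prior
        w = params.weights
        if np.any(np.diff(params.offsets_raw) <= 0) or np.any(w <= 0) or np.any(params.taus <= 0):
            return -math.inf
        ll += float(np.sum((cfg.dirichlet_alpha - 1.0) * np.log(w)))
        ll += float(np.sum(_norm_logpdf(params.offsets_raw, 0.0, cfg.offset_prior_scale)))
        ll += float(np.sum(_norm_logpdf(params.taus, 0.0, cfg.tau_prior_scale)))
        return ll

    def _record_base_for(self, params: FamilyParameters) -> np.ndarray:
        saved, self.params = self.params, params
        try:
            return self._record_base()
        finally:
            self.params = saved

    def _mh_shape(self, which: str) -> None:
        p, rng = self.params, self.rng
        cand = p.copy()
        extra = 0.0  # proposal-asymmetry / Jacobian corrections
        if which == "offsets":
            cand.offsets_raw = p.offsets_raw + rng.normal(0.0, self.step["offsets"], self.K)
        elif which == "taus":
            f = np.exp(rng.normal(0.0, self.step["taus"], self.K))
            cand.taus = p.taus * f
            extra = float(np.sum(np.log(f)))  # log-scale random walk Jacobian
        else:  # weights: Dirichlet proposal centred at the current point
            from scipy.stats import dirichlet

            conc = self.step["weights"]
            alpha_fwd = conc * p.weights + 1.0
            wstar = rng.dirichlet(alpha_fwd)
            if np.any(wstar <= 1e-12):
                return
            cand.weights = wstar
            alpha_rev = conc * wstar + 1.0
            extra = float(dirichlet.logpdf(p.weights, alpha_rev) - dirichlet.logpdf(wstar, alpha_fwd))
        self.accept[which][1] += 1
        logr = self._shape_ll(cand) - self._shape_ll(p) + extra
        if math.log(rng.random() + 1e-300) < logr:
            self.params = cand
            self.accept[which][0] += 1
            if self._adapting:
                self._tune(which, True)
        elif self._adapting:
            self._tune(which, False)

    def _tune(self, which: str, accepted: bool) -> None:
        g = 0.05
        target = 0.3
        move = g * ((1.0 if accepted else 0.0) - target)
        if which == "weights":
            self.step[which] = float(np.clip(self.step[which] * math.exp(-move * 4), 20.0, 5e4))
        else:
            self.step[which] = float(np.clip(self.step[which] * math.exp(move), 1e-3, 5.0))

    # hyperparameters -------------------------------------------------------
    def _update_hypers(self) -> None:
        p, cfg, d, rng = self.params, self.cfg, self.data, self.rng

        def slice_log_sd(name: str, logf_terms, scale: float) -> None:
            floor = max(1e-5, 1e-3 * scale)  # guards the variance-collapse funnel

            def logf(x: float) -> float:
                s = math.exp(x)
                if s < floor:
                    return -math.inf
                return logf_terms(s) + float(_norm_logpdf(s, 0.0, scale)) + x

            x0 = math.log(max(p.hypers[name], floor * 1.01))
            p.hypers[name] = math.exp(_slice_sample(logf, x0, rng))

        slice_log_sd("sd_ar", lambda s: float(np.sum(_norm_logpdf(p.ar, 0.0, s))), cfg.region_intercept_scale)
        slice_log_sd("sd_br", lambda s: float(np.sum(_norm_logpdf(p.br, 0.0, s))), cfg.region_slope_scale)
        slice_log_sd("sd_ac", lambda s: float(np.sum(_norm_logpdf(p.ac, 0.0, s))), cfg.country_intercept_scale)
        slice_log_sd("sd_bc", lambda s: float(np.sum(_norm_logpdf(p.bc, 0.0, s))), cfg.country_slope_scale)
        slice_log_sd("sd_u0", lambda s: rw2_logpdf(p.u0, s), cfg.rw2_scale_global)
        slice_log_sd("sd_ur", lambda s: sum(rw2_logpdf(p.ur[i], s) for i in range(d.R)), cfg.rw2_scale_region)
        slice_log_sd("sd_uc", lambda s: sum(rw2_logpdf(p.uc[i], s) for i in range(d.C)), cfg.rw2_scale_country)

        # design-variance components: the model means and prevalence stats do
        # not depend on these sigmas, so compute them once and vary only the
        # variances inside the slice evaluations
        from .model import prevalence_loglik_from_stats, prevalence_model_stats

        x_cur = self._x_from_params()
        if self.n_sm:
            mu_sm = self.A[: self.n_sm] @ x_cur
            if p.delta is not None:
                mu_sm = mu_sm + self.sm_cdelta * p.delta[self.sm_country]
        prev_stats = (
            prevalence_model_stats(p, d, mode=self.cfg.prevalence_mode) if self.has_prev else None
        )

        def design_terms(name: str):
            def terms(s: float) -> float:
                old = p.hypers[name]
                p.hypers[name] = s
                try:
                    ll = 0.0
                    if self.n_sm:
                        dv = _design_var(p, d.s_sub[self.sm_idx], d.s_agemis[self.sm_idx])
                        var = d.s_sd[self.sm_idx] ** 2 / d.s_n[self.sm_idx] + dv
                        ll += float(np.sum(_norm_logpdf(self.sm_y, mu_sm, np.sqrt(var))))
                    if prev_stats is not None:
                        dvf = _design_var(p, d.s_sub, d.s_agemis)
                        ll += prevalence_loglik_from_stats(d, prev_stats, dvf, self.cfg.prev_floor)
                    if d.n_ind_surveys:
                        evar = _design_var(p, d.isurv_sub, d.isurv_agemis)
                        ll += float(np.sum(_norm_logpdf(p.e, 0.0, np.sqrt(evar))))
                    return ll
                finally:
                    p.hypers[name] = old

            return terms

        slice_log_sd("sigma_ns", design_terms("sigma_ns"), cfg.sigma_ns_scale)
        if bool(np.any(d.s_sub)) or bool(np.any(d.isurv_sub)):
            slice_log_sd("sigma_sub", design_terms("sigma_sub"), cfg.sigma_sub_scale)
        if bool(np.any(d.s_agemis)) or bool(np.any(d.isurv_agemis)):
            slice_log_sd("sigma_age", design_terms("sigma_age"), cfg.sigma_age_scale)

        if self.is_women:
            from scipy.stats import norm as _norm

            def delta_terms(s: float) -> float:
                mu_r = p.mu_delta_region[d.region_idx]
                return float(
                    np.sum(
                        _norm_logpdf(p.delta, mu_r, s)
                        - np.log(np.clip(_norm.cdf(mu_r / s), 1e-300, None))
                    )
                )

            slice_log_sd("sigma_delta", delta_terms, cfg.sigma_delta_scale)
            sd_d = p.hypers["sigma_delta"]
            for ri in range(d.R):
                sel = d.region_idx == ri

                def logf(m: float, sel=sel) -> float:
                    t = float(
                        np.sum(
                            _norm_logpdf(p.delta[sel], m, sd_d)
                            - np.log(max(float(_norm.cdf(m / sd_d)), 1e-300))
                        )
                    )
                    return t + float(_norm_logpdf(m, p.mu_delta0, cfg.delta_region_scale))

                p.mu_delta_region[ri] = _slice_sample(logf, float(p.mu_delta_region[ri]), rng)
            # mu_delta0: conjugate normal given the region means
            prec = d.R / cfg.delta_region_scale**2 + 1.0 / cfg.delta_mu0_scale**2
            mean = (
                float(np.sum(p.mu_delta_region)) / cfg.delta_region_scale**2
                + cfg.delta_mu0_loc / cfg.delta_mu0_scale**2
            ) / prec
            p.mu_delta0 = float(rng.normal(mean, 1.0 / math.sqrt(prec)))

    # ---- iteration --------------------------------------------------------
    def iterate(self) -> None:
        self._update_z()
        self._update_location()
        self._update_delta()
        self._mh_shape("offsets")
        self._mh_shape("weights")
        self._mh_shape("taus")
        self._update_hypers()

    def snapshot(self) -> dict[str, np.ndarray | float]:
        p = self.params
        out: dict[str, np.ndarray | float] = {
            "a0": p.a0,
            "b0": p.b0,
            "ar": p.ar.copy(),
            "br": p.br.copy(),
            "ac": p.ac.copy(),
            "bc": p.bc.copy(),
            "u0": p.u0.copy(),
            "ur": p.ur.copy(),
            "uc": p.uc.copy(),
            "beta": p.beta.copy(),
            "e": p.e.copy(),
            "offsets_raw": p.offsets_raw.copy(),
            "weights": p.weights.copy(),
            "taus": p.taus.copy(),
            "hypers": np.array([p.hypers[n] for n in HYPER_NAMES]),
        }
        if self.is_women:
            out["delta"] = p.delta.copy()
            out["mu_delta_region"] = p.mu_delta_region.copy()
            out["mu_delta0"] = p.mu_delta0
        return out


# --------------------------------------------------------------------------
# posterior container
# --------------------------------------------------------------------------


@dataclass
class FamilyPosterior:
    """Retained draws of one family, kept per chain for diagnostics."""

    data: FamilyModelData
    draws: dict[str, np.ndarray]  # (chains, n_per_chain, ...) arrays
    target: int

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def S(self) -> int:
        return self.target

    def pooled(self, name: str) -> np.ndarray:
        a = self.draws[name]
        return a.reshape(a.shape[0] * a.shape[1], *a.shape[2:])[: self.target]

    def pooled_params(self, s: int) -> FamilyParameters:
        """Reconstruct the s-th pooled draw as a FamilyParameters object."""
        g = lambda n: self.pooled(n)[s]
        hy = self.pooled("hypers")[s]
        is_women = "delta" in self.draws
        return FamilyParameters(
            a0=float(g("a0")),
            b0=float(g("b0")),
            ar=g("ar"),
            br=g("br"),
            ac=g("ac"),
            bc=g("bc"),
            u0=g("u0"),
            ur=g("ur"),
            uc=g("uc"),
            beta=g("beta"),
            e=g("e"),
            offsets_raw=g("offsets_raw"),
            weights=g("weights"),
            taus=g("taus"),
            hypers={n: float(v) for n, v in zip(HYPER_NAMES, hy)},
            delta=g("delta") if is_women else None,
            mu_delta_region=g("mu_delta_region") if is_women else None,
            mu_delta0=float(g("mu_delta0")) if is_women else None,
        )


@dataclass
class PosteriorDraws:
    """Retained posterior draws for every fitted family, plus fit metadata."""

    families: dict[str, FamilyPosterior]
    meta: dict

    @property
    def S(self) -> int:
        return next(iter(self.families.values())).S

    def __getitem__(self, family: str) -> FamilyPosterior:
        return self.families[family]


def fit(
    family_data: Mapping[str, FamilyModelData] | FamilyModelData,
    model_cfg: ModelConfig = ModelConfig(),
    fit_cfg: FitConfig = FitConfig(),
    progress: bool = False,
) -> PosteriorDraws:
    """Fit the model by MCMC and pool exactly ``target_retained`` draws.

    ``family_data`` maps family name to its prepared dataset (a single
    dataset is accepted too).  Chains are independent and seeded from
    ``fit_cfg.seed``; the result is deterministic given data and configs.
    """
    if isinstance(family_data, FamilyModelData):
        family_data = {family_data.family: family_data}
    per_chain = fit_cfg.per_chain
    ss = np.random.SeedSequence(fit_cfg.seed)
    children = ss.spawn(len(family_data) * fit_cfg.chains)
    fams: dict[str, FamilyPosterior] = {}
    acc_meta: dict[str, dict] = {}
    t0 = time.time()
    for fi, (fam, data) in enumerate(sorted(family_data.items())):
        chain_draws: list[dict[str, np.ndarray]] = []
        acc: dict[str, list[int]] = {}
        for ch in range(fit_cfg.chains):
            rng = np.random.default_rng(children[fi * fit_cfg.chains + ch])
            smp = _FamilySampler(data, model_cfg, rng)
            for _ in range(fit_cfg.warmup):
                smp.iterate()
            smp._adapting = False
            store: dict[str, list] = {}
            for _ in range(per_chain):
                for _ in range(fit_cfg.thin):
                    smp.iterate()
                for name, val in smp.snapshot().items():
                    store.setdefault(name, []).append(np.asarray(val, dtype=float))
            chain_draws.append({n: np.stack(v) for n, v in store.items()})
            for k, (a, t) in smp.accept.items():
                acc.setdefault(k, [0, 0])
                acc[k][0] += a
                acc[k][1] += t
        draws = {n: np.stack([cd[n] for cd in chain_draws]) for n in chain_draws[0]}
        fams[fam] = FamilyPosterior(data=data, draws=draws, target=fit_cfg.target_retained)
        acc_meta[fam] = {k: (a / t if t else float("nan")) for k, (a, t) in acc.items()}
        if progress:
            print(f"[hbtrends] fitted family {fam} in {time.time() - t0:.1f}s")
    meta = {
        "seed": fit_cfg.seed,
        "chains": fit_cfg.chains,
        "warmup": fit_cfg.warmup,
        "thin": fit_cfg.thin,
        "target_retained": fit_cfg.target_retained,
        "per_chain": per_chain,
        "acceptance": acc_meta,
        "runtime_s": time.time() - t0,
    }
    return PosteriorDraws(families=fams, meta=meta)


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------


def diagnostics(pd_draws: PosteriorDraws, rhat_max: float = 1.05, ess_min: float = 100.0) -> pd.DataFrame:
    """Per-scalar-parameter split R-hat and effective sample size.

    With a single chain R-hat cannot be computed and is omitted with a
    warning.  The returned frame has one row per scalar parameter and a
    ``pass`` column at the documented thresholds; ``frame.attrs['pass']``
    aggregates it.
    """
    import arviz as az

    rows = []
    for fam, fp in pd_draws.families.items():
        single = fp.n_chains < 2
        if single:
            warnings.warn("single chain: R-hat omitted", stacklevel=2)
        flats = {
            name: arr.reshape(arr.shape[0], arr.shape[1], -1) for name, arr in fp.draws.items()
        }
        ds = az.from_dict({n: a for n, a in flats.items()}).posterior
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant parameters trigger div-by-zero
            rh_ds = az.rhat(ds) if not single else None
            ess_ds = az.ess(ds)
        for name, flat in flats.items():
            nscalar = flat.shape[2]
            rh_arr = np.asarray(rh_ds[name]).ravel() if rh_ds is not None else np.full(nscalar, np.nan)
            ess_arr = np.asarray(ess_ds[name]).ravel()
            const = flat.std(axis=(0, 1)) < 1e-12
            for j in range(nscalar):
                label = f"{fam}.{name}" + (f"[{j}]" if nscalar > 1 else "")
                rh = np.nan if const[j] else float(rh_arr[j])
                ess = float(flat.shape[0] * flat.shape[1]) if const[j] else float(ess_arr[j])
                ok = (np.isnan(rh) or rh <= rhat_max) and ess >= ess_min
                rows.append({"parameter": label, "rhat": rh, "ess": ess, "pass": ok})
    out = pd.DataFrame(rows)
    out.attrs["pass"] = bool(out["pass"].all())
    return out


def summary_row_theta_draws(fp: FamilyPosterior) -> np.ndarray:
    """Model mean (g/L) of every summary observation, per pooled draw (S, n)."""
    d = fp.data
    S = fp.S
    if d.n_summary == 0:
        return np.zeros((S, 0))
    a0 = fp.pooled("a0")
    b0 = fp.pooled("b0")
    ar, br = fp.pooled("ar"), fp.pooled("br")
    ac, bc = fp.pooled("ac"), fp.pooled("bc")
    u0, ur, uc = fp.pooled("u0"), fp.pooled("ur"), fp.pooled("uc")
    beta = fp.pooled("beta")
    r = d.region_idx[d.s_country]
    t = d.s_year - d.t_ref
    th = (
        a0[:, None]
        + ar[:, r]
        + ac[:, d.s_country]
        + (b0[:, None] + br[:, r] + bc[:, d.s_country]) * t[None, :]
        + u0[:, d.s_tidx]
        + ur[:, r, d.s_tidx]
        + uc[:, d.s_country, d.s_tidx]
        + beta @ d.X[d.s_country, d.s_tidx].T
    )
    if "delta" in fp.draws:
        delta = fp.pooled("delta")[:, d.s_country]
        pf = d.s_pregfrac[None, :]
        th = np.where(
            d.s_gcode[None, :] == G_PREGNANT,
            th - delta,
            np.where(d.s_gcode[None, :] == G_COMBINED, th - pf * delta, th),
        )
    return th


def posterior_predictive_check(pd_draws: PosteriorDraws, seed: int = 0) -> pd.DataFrame:
    """Central 95% posterior-predictive interval per summary observation.

    Returns one row per summary observation (mean-reporting sources) with an
    inside/outside indicator; aggregate coverage in ``frame.attrs['coverage']``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for fam, fp in pd_draws.families.items():
        d = fp.data
        if d.n_summary == 0:
            continue
        th = summary_row_theta_draws(fp)
        hy = fp.pooled("hypers")
        hmap = {n: hy[:, i] for i, n in enumerate(HYPER_NAMES)}
        dvar = (
            hmap["sigma_ns"][:, None] ** 2
            + np.where(d.s_sub[None, :], hmap["sigma_sub"][:, None] ** 2, 0.0)
            + np.where(d.s_agemis[None, :], hmap["sigma_age"][:, None] ** 2, 0.0)
        )
        var = d.s_sd[None, :] ** 2 / d.s_n[None, :] + dvar
        yrep = th + rng.standard_normal(th.shape) * np.sqrt(var)
        lo = np.quantile(yrep, 0.025, axis=0)
        hi = np.quantile(yrep, 0.975, axis=0)
        med = np.quantile(yrep, 0.5, axis=0)
        for i in range(d.n_summary):
            obs = d.s_mean[i]
            if np.isnan(obs):
                continue
            rows.append(
                {
                    "family": fam,
                    "row": i,
                    "observed": obs,
                    "pred_lo": lo[i],
                    "pred_med": med[i],
                    "pred_hi": hi[i],
                    "inside": bool(lo[i] <= obs <= hi[i]),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["coverage"] = float(out["inside"].mean()) if len(out) else float("nan")
    return out


# --------------------------------------------------------------------------
# persistence (text formats only)
# --------------------------------------------------------------------------


def save_draws(pd_draws: PosteriorDraws, out_dir) -> None:
    """Persist draws as one wide CSV per family plus a JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shapes: dict[str, dict] = {}
    for fam, fp in pd_draws.families.items():
        cols = {}
        shapes[fam] = {}
        for name, arr in fp.draws.items():
            flat = arr.reshape(arr.shape[0] * arr.shape[1], -1)
            shapes[fam][name] = list(arr.shape[2:])
            for j in range(flat.shape[1]):
                cols[f"{name}[{j}]"] = flat[:, j]
        pd.DataFrame(cols).to_csv(out / f"draws_{fam}.csv", index=False, float_format="%.17g")
        shapes[fam]["_chains"] = fp.n_chains
        shapes[fam]["_per_chain"] = next(iter(fp.draws.values())).shape[1]
        shapes[fam]["_target"] = fp.target
    with open(out / "draws_meta.json", "w") as fh:
        json.dump({"meta": pd_draws.meta, "shapes": shapes}, fh, indent=1, default=str)


def load_draws(in_dir, family_data: Mapping[str, FamilyModelData]) -> PosteriorDraws:
    """Reload draws written by :func:`save_draws`, reattaching the datasets."""
    inp = Path(in_dir)
    with open(inp / "draws_meta.json") as fh:
        meta = json.load(fh)
    fams = {}
    for fam, shp in meta["shapes"].items():
        df = pd.read_csv(inp / f"draws_{fam}.csv", float_precision="round_trip")
        chains, per_chain = shp["_chains"], shp["_per_chain"]
        draws = {}
        for name, tail in shp.items():
            if name.startswith("_"):
                continue
            ncol = int(np.prod(tail)) if tail else 1
            mat = np.column_stack([df[f"{name}[{j}]"].to_numpy() for j in range(ncol)])
            draws[name] = mat.reshape(chains, per_chain, *tail)
        fams[fam] = FamilyPosterior(data=family_data[fam], draws=draws, target=shp["_target"])
    return PosteriorDraws(families=fams, meta=meta["meta"])
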
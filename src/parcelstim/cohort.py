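"""Synthetic cohorts: reference subjects, anomalous patients, outcomes.

Replaces the undeposited study data with generators whose statistical
structure matches what the downstream analysis assumes:

* Reference subjects follow a latent network-factor model — one latent
  series per large-scale network, correlated across networks, plus
  parcel-specific noise. With loadings ``a = noise_sd * sqrt(w/(1-w))``
  and latent cross-correlation ``r = b/w``, the implied population
  covariance is::

      Var(x_p)        = a^2 + (m_p * noise_sd)^2
      Cov(x_p, x_q)   = a^2 * w_latent   with  a^2 = noise_sd^2 w/(1-w)

  so for parcels with the baseline noise multiplier ``m_p = 1`` the
  ``within_network_coupling`` (w) and ``between_network_coupling`` (b)
  are exactly the population correlations. A small designated subset of
  parcels (the last ``noisy_parcel_fraction`` of the atlas) carries an
  inflated noise multiplier, emulating the artifact-dominated regions
  whose principal components the CompCor-style confound step is designed
  to remove; without such a stable noise pool the confound regression
  would strip random shared-signal directions instead and distort the
  normative calibration. Each subject additionally jitters its
  per-network loadings (``coupling_jitter_sd``), giving network-coupled
  edges genuinely elevated cross-subject variance — the heterogeneous
  edge-variance profile that the highest-variance-third exclusion step
  presumes.

* Patients are reference subjects whose *population* edge coupling is
  shifted on chosen edges so that the expected downstream tangent z-score
  equals a requested magnitude. The shift is calibrated empirically by
  pushing probe subjects through the full pipeline (preprocessing included),
  because confound regression and shrinkage attenuate injected covariance.

* Outcome records emulate score trajectories: BDI baselines around the
  study cohort's mean, post/follow-up scores constructed to achieve
  requested responder/remitter fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .atlas import NETWORKS
from .preprocess import TimeSeriesMatrix
from .pipeline import PipelineParams, ReferenceFit, fit_reference


class CohortError(ValueError):
    pass


def default_partition(n_parcels: int, networks=NETWORKS) -> tuple:
    """Even split of parcels over the four canonical networks."""
    per = np.full(len(networks), n_parcels // len(networks))
    per[: n_parcels % len(networks)] += 1
    labels = []
    for net, cnt in zip(networks, per):
        labels.extend([net] * int(cnt))
    return tuple(labels)


@dataclass(frozen=True)
class CohortSpec:
    """Reference-cohort generating conditions.

    Defaults mirror the study's acquisition and normative sample: 200
    reference subjects, 128 volumes at TR 2.8 s; 60 parcels (4 networks
    x 15) is the test scale, 377 the full-scale parity run.
    """

    n_reference: int = 200
    n_timepoints: int = 128
    sampling_interval: float = 2.8
    n_parcels: int = 60
    network_partition: tuple = None
    within_network_coupling: float = 0.35
    between_network_coupling: float = 0.12
    noise_sd: float = 1.0
    noisy_parcel_fraction: float = 0.1
    noisy_noise_multiplier: float = 3.0
    coupling_jitter_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_reference < 2:
            raise CohortError("n_reference must be >= 2")
        if self.n_timepoints < 4:
            raise CohortError("n_timepoints must be >= 4")
        w, b = self.within_network_coupling, self.between_network_coupling
        if not (0 <= w < 1) or not (0 <= b < 1):
            raise CohortError("couplings must lie in [0, 1)")
        if b > w:
            raise CohortError(
                "between-network coupling cannot exceed within-network")
        if self.noise_sd <= 0:
            raise CohortError(
                "noise_sd must be positive: with zero idiosyncratic noise "
                "the implied covariance is degenerate (zero-variance or "
                "perfectly collinear parcels)")
        if self.network_partition is None:
            object.__setattr__(self, "network_partition",
                               default_partition(self.n_parcels))
        if len(self.network_partition) != self.n_parcels:
            raise CohortError("network_partition length != n_parcels")
        # latent correlation matrix must be positive definite
        k = len(set(self.network_partition))
        r = b / w if w > 0 else 0.0
        if w > 0 and k > 1 and not (-1.0 / (k - 1) < r < 1.0):
            raise CohortError(
                f"latent correlation {r:.3f} over {k} networks is not "
                "positive definite: reduce between_network_coupling")
        if not 0 <= self.noisy_parcel_fraction < 1:
            raise CohortError("noisy_parcel_fraction must be in [0, 1)")
        if self.noisy_noise_multiplier < 1:
            raise CohortError("noisy_noise_multiplier must be >= 1")
        if not 0 <= self.coupling_jitter_sd < 0.5:
            raise CohortError("coupling_jitter_sd must be in [0, 0.5)")
        if self.n_timepoints <= self.n_parcels:
            warnings.warn(
                f"n_timepoints ({self.n_timepoints}) <= n_parcels "
                f"({self.n_parcels}): sample covariance is rank-deficient, "
                "shrinkage regularization is mandatory downstream",
                stacklevel=2)

    @property
    def networks(self) -> tuple:
        return tuple(dict.fromkeys(self.network_partition))

    def loading(self) -> float:
        w = self.within_network_coupling
        return self.noise_sd * np.sqrt(w / (1 - w)) if w > 0 else 0.0

    def latent_correlation(self) -> np.ndarray:
        nets = self.networks
        k = len(nets)
        w, b = self.within_network_coupling, self.between_network_coupling
        r = b / w if w > 0 else 0.0
        lat = np.full((k, k), r)
        np.fill_diagonal(lat, 1.0)
        return lat

    def noise_multipliers(self) -> np.ndarray:
        """Per-parcel noise SD multiplier: 1 except for the designated
        high-noise pool at the end of the parcel list."""
        m = np.ones(self.n_parcels)
        n_noisy = int(np.ceil(self.noisy_parcel_fraction * self.n_parcels))
        if n_noisy:
            m[-n_noisy:] = self.noisy_noise_multiplier
        return m

    def population_covariance(self) -> np.ndarray:
        """Implied parcel covariance of the latent-factor model."""
        nets = self.networks
        idx = {n: i for i, n in enumerate(nets)}
        member = np.array([idx[n] for n in self.network_partition])
        a = self.loading()
        lat = self.latent_correlation()
        sigma = a ** 2 * lat[np.ix_(member, member)]
        noise_var = (self.noise_multipliers() * self.noise_sd) ** 2
        sigma[np.diag_indices_from(sigma)] += noise_var
        return sigma


@dataclass(frozen=True)
class AnomalyInjectionSpec:
    """Edges to perturb: (parcel_i, parcel_j, direction, magnitude).

    direction is "hyper" or "hypo"; magnitude is the target |z| in the
    normative tangent space.
    """

    edges: tuple
    seed: int = 0

    def __post_init__(self):
        seen = set()
        norm = []
        for e in self.edges:
            i, j, direction, mag = e
            i, j = int(i), int(j)
            if i == j:
                raise CohortError(f"self-edge ({i},{i}) cannot be injected")
            if direction not in ("hyper", "hypo"):
                raise CohortError(f"direction must be hyper/hypo: {e}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise CohortError(f"edge {key} listed more than once")
            seen.add(key)
            if mag == 0:
                warnings.warn(f"edge {key}: magnitude 0 is undetectable "
                              "by construction", stacklevel=2)
            norm.append((key[0], key[1], direction, float(mag)))
        object.__setattr__(self, "edges", tuple(norm))


def _membership(spec: CohortSpec) -> np.ndarray:
    idx = {n: i for i, n in enumerate(spec.networks)}
    return np.array([idx[n] for n in spec.network_partition])


def _subject_loadings(spec: CohortSpec, rng) -> np.ndarray:
    """Per-network loading for one subject: a * (1 + gamma_k), with
    gamma ~ N(0, coupling_jitter_sd^2) clipped away from degeneracy."""
    k = len(spec.networks)
    gamma = np.clip(rng.normal(0.0, spec.coupling_jitter_sd, size=k),
                    -0.8, 0.8)
    return spec.loading() * (1.0 + gamma)


def _sample_factor_subject(spec: CohortSpec, rng) -> np.ndarray:
    """One subject from the latent network-factor model (loadings
    jittered per subject)."""
    member = _membership(spec)
    loadings = _subject_loadings(spec, rng)
    chol = np.linalg.cholesky(spec.latent_correlation())
    latents = chol @ rng.standard_normal(
        (len(spec.networks), spec.n_timepoints))
    noise = rng.standard_normal((spec.n_parcels, spec.n_timepoints))
    noise_sd = (spec.noise_multipliers() * spec.noise_sd)[:, None]
    return loadings[member][:, None] * latents[member] + noise_sd * noise


def _subject_covariance(spec: CohortSpec, rng) -> np.ndarray:
    """Implied covariance for one subject's jittered loadings (draws
    the same per-network gamma as the factor sampler would)."""
    member = _membership(spec)
    loadings = _subject_loadings(spec, rng)
    lat = spec.latent_correlation()
    a = loadings[member]
    sigma = np.outer(a, a) * lat[np.ix_(member, member)]
    noise_var = (spec.noise_multipliers() * spec.noise_sd) ** 2
    sigma[np.diag_indices_from(sigma)] += noise_var
    return sigma


def generate_reference_cohort(spec: CohortSpec) -> list:
    """Draw the reference cohort; deterministic under a fixed spec/seed."""
    rng = np.random.default_rng(spec.seed)
    cohort = []
    for s in range(spec.n_reference):
        values = _sample_factor_subject(spec, rng)
        cohort.append(TimeSeriesMatrix(
            values=values,
            meta={"subject": f"ref{s:04d}", "seed": spec.seed,
                  "sampling_interval_s": spec.sampling_interval}))
    return cohort


# ---------------------------------------------------------------------------
# Patient generation with calibrated edge injection
# ---------------------------------------------------------------------------

@dataclass
class InjectionCalibration:
    """Per-edge covariance shifts realizing the requested tangent z.

    Calibrated against a specific fitted reference; stored so replicate
    patients can reuse it.
    """

    edges: tuple                      # as in AnomalyInjectionSpec
    deltas: np.ndarray                # signed covariance shift per edge
    probe_log: dict = field(default_factory=dict)


_REFERENCE_CACHE: dict = {}


def _internal_reference(spec: CohortSpec,
                        params: PipelineParams) -> ReferenceFit:
    key = (spec, params)
    if key not in _REFERENCE_CACHE:
        _REFERENCE_CACHE[key] = fit_reference(
            generate_reference_cohort(spec), params)
    return _REFERENCE_CACHE[key]


def _delta_matrix(n_parcels, edges, deltas):
    delta = np.zeros((n_parcels, n_parcels))
    for (i, j, _, _), d in zip(edges, deltas):
        delta[i, j] += d
        delta[j, i] += d
    return delta


def _scale_into_pd(spec, edges, deltas, margin: float = 0.15):
    """Common down-scaling of edge shifts so the implied covariance keeps
    a positive-definiteness margin (fraction of the unperturbed minimum
    eigenvalue). Leaves feasible shifts untouched."""
    sigma = spec.population_covariance()
    floor = margin * np.linalg.eigvalsh(sigma)[0]
    scale = 1.0
    for _ in range(30):
        d = _delta_matrix(spec.n_parcels, edges, scale * deltas)
        if np.linalg.eigvalsh(sigma + d)[0] >= floor:
            break
        scale *= 0.85
    return scale * np.asarray(deltas, float)


def _mean_injected_z(spec, edges, deltas, reference, rng, n_probe):
    """Mean realized z at each injected edge over probe subjects pushed
    through the full pipeline."""
    delta = _delta_matrix(spec.n_parcels, edges, deltas)
    w = np.linalg.eigvalsh(spec.population_covariance() + delta)[0]
    if w <= 0:
        raise CohortError(
            f"injected covariance not positive definite (min eig {w:.3g}); "
            "reduce magnitude")
    res = reference.results
    eidx = {(min(i, j), max(i, j)): None for (i, j, _, _) in edges}
    # map unordered pairs to edge positions in the results arrays
    lookup = {(a, b): k for k, (a, b) in
              enumerate(zip(res.edge_i, res.edge_j))}
    for key in eidx:
        if key not in lookup:
            raise CohortError(f"edge {key} outside parcel range")
        if res.excluded[lookup[key]]:
            raise CohortError(
                f"edge {key} is variance-excluded in the reference model; "
                "its z is undefined — inject a non-excluded edge")
        eidx[key] = lookup[key]
    zsum = np.zeros(len(edges))
    for _ in range(n_probe):
        sigma_s = _subject_covariance(spec, rng) + delta
        ws = np.linalg.eigvalsh(sigma_s)[0]
        if ws <= 0:
            raise CohortError(
                f"injected subject covariance not positive definite "
                f"(min eig {ws:.3g}); reduce magnitude")
        chol = np.linalg.cholesky(sigma_s)
        values = chol @ rng.standard_normal(
            (spec.n_parcels, spec.n_timepoints))
        ts = TimeSeriesMatrix(values=values)
        a = res.score(reference.subject_tangent(ts))
        for k, (i, j, _, _) in enumerate(edges):
            zsum[k] += a.z[eidx[(min(i, j), max(i, j))]]
    return zsum / n_probe


def calibrate_injection(spec: CohortSpec, inject: AnomalyInjectionSpec,
                        reference: ReferenceFit = None,
                        n_probe: int = 24,
                        params: PipelineParams = PipelineParams(),
                        ) -> InjectionCalibration:
    """Find the population-covariance shift per edge whose expected
    downstream tangent z equals the requested signed magnitude.

    Two-stage probe: a fixed probe amplitude gives a linear estimate; a
    second probe at the estimated amplitude applies one multiplicative
    Newton correction for the tangent map's nonlinearity.
    """
    if reference is None:
        reference = _internal_reference(spec, params)
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=(int(inject.seed) % (2 ** 31), 0xCA11B)))
    edges = inject.edges
    signs = np.array([1.0 if d == "hyper" else -1.0
                      for (_, _, d, _) in edges])
    targets = signs * np.array([m for (_, _, _, m) in edges])
    probe0 = _scale_into_pd(spec, edges, signs * 0.3)
    z0 = _mean_injected_z(spec, edges, probe0, reference, rng, n_probe)
    slope = np.where(np.abs(z0) > 1e-9, z0 / probe0, np.nan)
    if np.any(~np.isfinite(slope)) or np.any(slope <= 0.1):
        # weak/noisy response (small reference cohorts inflate normative
        # SDs): remeasure with three times the probe subjects
        z0 = _mean_injected_z(spec, edges, probe0, reference, rng,
                              3 * n_probe)
        slope = np.where(np.abs(z0) > 1e-9, z0 / probe0, np.nan)
    if np.any(~np.isfinite(slope)) or np.any(slope <= 0):
        raise CohortError("probe produced non-positive z response; "
                          "cannot calibrate injection")
    est = targets / slope
    # keep the second probe inside the positive-definite cone: scale all
    # shifts down jointly if the linear estimate overshoots the budget
    est = _scale_into_pd(spec, edges, est)
    z1 = _mean_injected_z(spec, edges, est, reference, rng, n_probe)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(np.abs(z1) > 1e-9, targets / z1, 1.0)
    deltas = est * np.clip(corr, 0.5, 2.0)
    # magnitude-0 edges: delta exactly 0
    deltas[targets == 0] = 0.0
    scaled = _scale_into_pd(spec, edges, deltas)
    pd_scale = 1.0
    if not np.allclose(scaled, deltas):
        pd_scale = float(scaled[np.argmax(np.abs(deltas))]
                         / deltas[np.argmax(np.abs(deltas))])
        warnings.warn(
            f"requested injection magnitudes exceed the positive-definite "
            f"budget of the population covariance; shifts scaled by "
            f"{pd_scale:.2f} (realized z will fall short of the request)",
            stacklevel=2)
        deltas = scaled
    return InjectionCalibration(
        edges=edges, deltas=deltas,
        probe_log={"probe0": probe0.tolist(), "z0": z0.tolist(),
                   "estimate": est.tolist(), "z1": z1.tolist(),
                   "n_probe": n_probe, "pd_scale": pd_scale})


def generate_patient(spec: CohortSpec, inject: AnomalyInjectionSpec,
                     seed: int = None, reference: ReferenceFit = None,
                     calibration: InjectionCalibration = None,
                     params: PipelineParams = PipelineParams(),
                     ) -> TimeSeriesMatrix:
    """One synthetic patient whose population coupling is shifted on the
    injected edges; all other edges follow the reference model.

    With an empty injection list the patient is statistically
    exchangeable with reference subjects.
    """
    if seed is None:
        seed = inject.seed
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    sigma = _subject_covariance(spec, rng)
    if inject.edges:
        if calibration is None:
            calibration = calibrate_injection(spec, inject,
                                              reference=reference,
                                              params=params)
        sigma = sigma + _delta_matrix(spec.n_parcels, inject.edges,
                                      calibration.deltas)
        w = np.linalg.eigvalsh(sigma)[0]
        if w <= 0:
            raise CohortError(
                f"patient covariance not positive definite after injection "
                f"(min eig {w:.3g}); reduce magnitude")
        deltas = calibration.deltas.tolist()
    else:
        deltas = []
    chol = np.linalg.cholesky(sigma)
    values = chol @ rng.standard_normal((spec.n_parcels, spec.n_timepoints))
    return TimeSeriesMatrix(
        values=values,
        meta={"subject": "patient", "seed": int(seed),
              "injected_edges": [list(e) for e in inject.edges],
              "injection_deltas": deltas,
              "sampling_interval_s": spec.sampling_interval})


# ---------------------------------------------------------------------------
# Outcome trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectProfile:
    """Requested cohort-level outcome structure.

    Defaults reproduce the study cohort's printed rates: 8/26 post
    responders, 16/26 post remitters, 7/26 lost to follow-up, 11/19 and
    13/19 responders/remitters among follow-up completers, 7/26 TRD.
    """

    responder_fraction: float = 8 / 26
    remitter_fraction: float = 16 / 26
    follow_up_loss: float = 7 / 26
    fu_responder_fraction: float = 11 / 19
    fu_remitter_fraction: float = 13 / 19
    trd_fraction: float = 7 / 26
    bdi_baseline_mean: float = 25.2
    bdi_baseline_sd: float = 7.7
    eq5d_baseline_mean: float = 0.524
    eq5d_baseline_sd: float = 0.223
    followup_interval_mean_months: float = 2.6
    followup_interval_sd_months: float = 2.4

    def __post_init__(self):
        for name in ("responder_fraction", "remitter_fraction",
                     "follow_up_loss", "fu_responder_fraction",
                     "fu_remitter_fraction", "trd_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise CohortError(f"{name} must lie in [0, 1]")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    from scipy.stats import truncnorm
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                         random_state=rng)

# Response requires (baseline - later)/baseline >= 0.47, i.e.
# later <= (1 - 0.47) * baseline; remission requires later <= 12.
_RESPONSE_DROP = 0.47
_REMISSION_CUTOFF = 12


def _later_score(rng, baseline, responder, remitter):
    """Integer later score consistent with the requested labels."""
    resp_max = int(np.floor((1 - _RESPONSE_DROP) * baseline))
    if responder and remitter:
        hi = min(resp_max, _REMISSION_CUTOFF)
        lo = 0
    elif responder:  # response without remission needs later > 12
        lo, hi = _REMISSION_CUTOFF + 1, resp_max
    elif remitter:  # remission without response needs later > 0.53*b
        lo, hi = resp_max + 1, _REMISSION_CUTOFF
    else:
        lo, hi = max(resp_max, _REMISSION_CUTOFF) + 1, int(baseline) + 3
    hi = min(hi, 63)
    if lo > hi:
        return None
    return int(rng.integers(lo, hi + 1))


def _label_demands(n, n_resp, n_rem):
    """How many remit-only / respond-only labels the assignment needs."""
    n_both = max(min(n_resp, n_rem), n_resp + n_rem - n)
    return n_rem - n_both, n_resp - n_both


def _redraw_for_feasibility(rng, baselines, idx_pool, need_low, need_high,
                            mean, sd):
    """Redraw a few baselines so the requested label mix is achievable.

    Remission without response needs baseline <= 22; response without
    remission needs baseline >= 25. When the draw is short of such
    subjects, the most extreme baselines in the pool are redrawn from the
    truncated normal restricted to the feasible band.
    """
    idx_pool = list(idx_pool)
    low = [k for k in idx_pool if baselines[k] <= 22]
    short = need_low - len(low)
    if short > 0:
        for k in sorted(idx_pool, key=lambda k: -baselines[k])[:short]:
            baselines[k] = int(round(_truncated_normal(
                rng, mean, sd, 1, 22, 1)[0]))
    high = [k for k in idx_pool if baselines[k] >= 25]
    short = need_high - len(high)
    if short > 0:
        for k in sorted(idx_pool, key=lambda k: baselines[k])[:short]:
            baselines[k] = int(round(_truncated_normal(
                rng, mean, sd, 25, 63, 1)[0]))


def _assign_labels(rng, baselines, n_resp, n_rem):
    """Feasible responder/remitter label assignment.

    A responder-non-remitter needs a post score in (12, 0.53*baseline],
    feasible only for baseline >= 25; a remitter-non-responder needs
    (0.53*baseline, 12], feasible only for baseline <= 22. Constrained
    labels are placed on the best-suited baselines first; only a
    genuinely infeasible leftover escalates to responder+remitter (always
    feasible), so requested counts are met whenever the baselines allow.
    """
    n = len(baselines)
    n_both = min(n_resp, n_rem)  # responders typically also remit
    n_both = max(n_both, n_resp + n_rem - n)
    labels = ([(True, True)] * n_both
              + [(True, False)] * (n_resp - n_both)
              + [(False, True)] * (n_rem - n_both))
    labels += [(False, False)] * (n - len(labels))
    out = [None] * n
    remaining = list(labels)
    free = set(range(n))

    def place(want, candidates):
        for k in candidates:
            if want not in remaining:
                return
            out[k] = want
            remaining.remove(want)
            free.discard(k)

    asc = sorted(free, key=lambda k: (baselines[k], rng.random()))
    # remit-only on the lowest feasible baselines
    place((False, True), [k for k in asc
                          if np.floor(0.53 * baselines[k]) + 1 <= 12])
    # resp-only on the highest feasible baselines
    place((True, False), [k for k in reversed(asc)
                          if k in free and np.floor(0.53 * baselines[k]) > 12])
    # neither needs baseline >= 10
    place((False, False), [k for k in asc
                           if k in free and baselines[k] >= 10])
    place((True, True), [k for k in asc if k in free])
    # leftovers: escalate to the always-feasible both-label
    for k in sorted(free):
        out[k] = remaining.pop() if remaining else (False, False)
        if out[k] == (True, False) and np.floor(0.53 * baselines[k]) <= 12:
            out[k] = (True, True)
        if out[k] == (False, True) and np.floor(0.53 * baselines[k]) + 1 > 12:
            out[k] = (True, True)
        if out[k] == (False, False) and baselines[k] < 10:
            out[k] = (False, True)
    return out


def generate_outcomes(n_patients: int,
                      effect_profile: EffectProfile = EffectProfile(),
                      seed: int = 0) -> list:
    """Synthetic BDI / EQ-5D trajectories hitting the requested
    responder/remitter fractions; returns a list of OutcomeRecord."""
    from .outcomes import OutcomeRecord

    if n_patients < 1:
        raise CohortError("need at least one patient")
    p = effect_profile
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    baselines = np.round(_truncated_normal(
        rng, p.bdi_baseline_mean, p.bdi_baseline_sd, 1, 63,
        n_patients)).astype(int)
    n_resp = int(round(p.responder_fraction * n_patients))
    n_rem = int(round(p.remitter_fraction * n_patients))

    n_lost = int(round(p.follow_up_loss * n_patients))
    completers = np.zeros(n_patients, dtype=bool)
    completers[rng.choice(n_patients, n_patients - n_lost,
                          replace=False)] = True
    n_fu = int(completers.sum())
    fu_resp = int(round(p.fu_responder_fraction * n_fu))
    fu_rem = int(round(p.fu_remitter_fraction * n_fu))

    # make the requested label mix achievable under the drawn baselines
    need_low, need_high = _label_demands(n_patients, n_resp, n_rem)
    _redraw_for_feasibility(rng, baselines, range(n_patients), need_low,
                            need_high, p.bdi_baseline_mean,
                            p.bdi_baseline_sd)
    fu_low, fu_high = _label_demands(n_fu, fu_resp, fu_rem)
    _redraw_for_feasibility(rng, baselines, np.flatnonzero(completers),
                            fu_low, fu_high, p.bdi_baseline_mean,
                            p.bdi_baseline_sd)

    post_labels = _assign_labels(rng, baselines, n_resp, n_rem)
    fu_labels_sub = _assign_labels(rng, baselines[completers],
                                   fu_resp, fu_rem)
    fu_labels = [None] * n_patients
    for k, idx in enumerate(np.flatnonzero(completers)):
        fu_labels[idx] = fu_labels_sub[k]

    n_trd = int(round(p.trd_fraction * n_patients))
    trd = np.zeros(n_patients, dtype=bool)
    trd[rng.choice(n_patients, n_trd, replace=False)] = True

    eq_base = np.clip(rng.normal(p.eq5d_baseline_mean, p.eq5d_baseline_sd,
                                 n_patients), -1, 1)
    records = []
    for k in range(n_patients):
        b = int(baselines[k])
        post = _later_score(rng, b, *post_labels[k])
        if post is None:  # infeasible corner (tiny baselines); no change
            post = b
        eq_post = float(np.clip(eq_base[k] + rng.normal(0.21, 0.12), -1, 1))
        if completers[k]:
            fu = _later_score(rng, b, *fu_labels[k])
            if fu is None:
                fu = post
            eq_fu = float(np.clip(eq_base[k] + rng.normal(0.19, 0.12),
                                  -1, 1))
            interval = float(max(1.0, rng.normal(
                p.followup_interval_mean_months,
                p.followup_interval_sd_months)))
        else:
            fu, eq_fu, interval = None, None, 0.0
        records.append(OutcomeRecord(
            patient_id=f"p{k:03d}", bdi_baseline=b, bdi_post=int(post),
            bdi_followup=None if fu is None else int(fu),
            eq5d_baseline=float(eq_base[k]), eq5d_post=eq_post,
            eq5d_followup=eq_fu, trd=bool(trd[k]),
            followup_interval_months=interval))
    return records
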
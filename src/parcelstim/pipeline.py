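"""Per-subject analysis pipeline and reference-cohort fitting.

Binds the stages together with one parameter set: preprocessing
(DVARS scrubbing, detrending, CompCor-style confounds, variance
normalization), shrinkage-regularized covariance, Frechet-mean reference,
tangent embedding, and the normative fit. ``run_pipeline`` at the bottom
drives a full synthetic study end to end and writes all artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .preprocess import TimeSeriesMatrix, preprocess
from .connectivity import (frechet_mean, subject_connectivity, tangent_embed)
from .normative import (NormativeConnectivity, NormativeConnectivityResults,
                        render_anomaly_heatmap)


@dataclass(frozen=True)
class PipelineParams:
    """Stage parameters; the defaults reproduce the study constants
    (3-sigma threshold, exclusion of the highest-variance third of edge
    pairs, 30-mm depth cap, 3-target maximum are held downstream)."""

    dvars_sigma: float = 2.0
    compcor_components: int = 5
    detrend_order: int = 2
    shrinkage: float = 0.1
    frechet_tol: float = 1e-6
    frechet_max_iter: int = 50
    sigma: float = 3.0
    exclude_fraction: float = 1.0 / 3.0


@dataclass
class ReferenceFit:
    """Reference-cohort geometry plus the fitted normative model."""

    mean: np.ndarray  # Frechet mean of regularized covariances
    results: NormativeConnectivityResults
    params: PipelineParams
    n_reference: int

    def subject_tangent(self, ts: TimeSeriesMatrix) -> np.ndarray:
        """Preprocess one subject and embed at the reference mean."""
        clean = preprocess(
            ts, dvars_sigma=self.params.dvars_sigma,
            compcor_components=self.params.compcor_components,
            detrend_order=self.params.detrend_order)
        cov = subject_connectivity(clean, shrinkage=self.params.shrinkage)
        return tangent_embed(cov, self.mean)

    def score_subject(self, ts: TimeSeriesMatrix, subject_id=None):
        return self.results.score(self.subject_tangent(ts),
                                  subject_id=subject_id)


def fit_reference(cohort, params: PipelineParams = PipelineParams(),
                  parcel_ids=None, min_subjects: int = 10) -> ReferenceFit:
    """Fit the reference geometry and normative model from raw cohort
    time series (list of :class:`TimeSeriesMatrix`)."""
    covs = []
    for ts in cohort:
        clean = preprocess(ts, dvars_sigma=params.dvars_sigma,
                           compcor_components=params.compcor_components,
                           detrend_order=params.detrend_order)
        covs.append(subject_connectivity(clean, shrinkage=params.shrinkage))
    mean = frechet_mean(covs, tol=params.frechet_tol,
                        max_iter=params.frechet_max_iter)
    tangents = np.stack([tangent_embed(c, mean) for c in covs])
    if parcel_ids is None and cohort:
        parcel_ids = cohort[0].parcel_ids
    results = NormativeConnectivity(
        tangents, parcel_ids, min_subjects=min_subjects).fit(
            exclude_fraction=params.exclude_fraction, sigma=params.sigma)
    return ReferenceFit(mean=mean, results=results, params=params,
                        n_reference=len(covs))


def _greedy_clique(edge_i, edge_j, allowed, size):
    """Greedily grow a clique over `allowed` nodes within the given edge
    set (order: first-come neighbors); raises if none of `size` exists."""
    adj = {}
    allowed = set(int(a) for a in allowed)
    for a, b in zip(edge_i, edge_j):
        a, b = int(a), int(b)
        if a in allowed and b in allowed:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    for seed_node in sorted(adj):
        clique = [seed_node]
        for cand in sorted(adj[seed_node]):
            if all(cand in adj.get(c, ()) for c in clique):
                clique.append(cand)
                if len(clique) == size:
                    return clique
    raise RuntimeError(f"no clique of size {size} among candidate edges")


# ---------------------------------------------------------------------------
# Whole-study driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Resolved configuration for one end-to-end synthetic run."""

    seed: int = 0
    n_parcels: int = 60
    n_reference: int = 200
    n_timepoints: int = 128
    sampling_interval: float = 2.8
    params: PipelineParams = field(default_factory=PipelineParams)
    networks_in_scope: tuple = ("DMN", "CEN", "Salience")
    max_targets: int = 3
    depth_max_mm: float = 30.0
    min_burden: int = 3
    injected_edges: tuple = ()  # ((i, j, direction, magnitude), ...)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = asdict(self.params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "params" in d and isinstance(d["params"], dict):
            d["params"] = PipelineParams(**d["params"])
        if "injected_edges" in d:
            d["injected_edges"] = tuple(tuple(e) for e in d["injected_edges"])
        if "networks_in_scope" in d:
            d["networks_in_scope"] = tuple(d["networks_in_scope"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run simulate -> preprocess -> connect -> normative fit -> score ->
    prescribe -> protocol -> report on synthetic data; returns a manifest
    of written artifacts."""
    from .atlas import synthetic_atlas
    from .cohort import (CohortSpec, AnomalyInjectionSpec,
                         generate_reference_cohort, generate_patient)
    from .prescribe import prescribe_targets
    from .protocol import TBSParams, SessionSchedule, build_session, \
        build_course
    from .connectivity import matrix_to_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "artifacts": {}}

    def _write(name, fn):
        path = outdir / name
        fn(path)
        manifest["artifacts"][name] = str(path)

    atlas = synthetic_atlas(config.n_parcels, seed=config.seed)
    _write("atlas.tsv", atlas.to_tsv)

    spec = CohortSpec(
        n_reference=config.n_reference, n_timepoints=config.n_timepoints,
        sampling_interval=config.sampling_interval,
        n_parcels=config.n_parcels,
        network_partition=tuple(atlas.networks), seed=config.seed)
    cohort = generate_reference_cohort(spec)
    ref = fit_reference(cohort, config.params)
    _write("normative_model.tsv", ref.results.to_tsv)
    _write("frechet_mean.tsv",
           lambda p: matrix_to_tsv(ref.mean, p, atlas.parcel_ids))

    if config.injected_edges:
        inject = AnomalyInjectionSpec(
            edges=tuple(tuple(e) for e in config.injected_edges),
            seed=config.seed + 1)
    else:
        # default demonstration patient: hyper anomalies concentrated on
        # one in-scope parcel, plus one hypo edge
        ok = ~ref.results.excluded
        iu, ju = ref.results.edge_i, ref.results.edge_j
        in_scope = atlas.parcels_in(config.networks_in_scope)
        cand = np.flatnonzero(ok & in_scope[iu] & in_scope[ju])
        reachable = (in_scope & atlas.is_cortical()
                     & (atlas.depths <= config.depth_max_mm))
        # hyperconnect a clique of stimulable parcels (cliques perturb
        # the covariance far less than star patterns of the same burden)
        clique = _greedy_clique(iu[cand], ju[cand],
                                np.flatnonzero(reachable), size=4)
        edges = [(int(a), int(b), "hyper", 5.0)
                 for k, a in enumerate(clique) for b in clique[k + 1:]]
        clique_set = set(clique)
        other = next(e for e in cand
                     if not {int(iu[e]), int(ju[e])} & clique_set)
        edges.append((int(iu[other]), int(ju[other]), "hypo", 5.0))
        inject = AnomalyInjectionSpec(edges=tuple(edges),
                                      seed=config.seed + 1)
    patient = generate_patient(spec, inject, reference=ref)
    _write("patient_timeseries.tsv", patient.to_tsv)
    with open(outdir / "injection_truth.json", "w") as fh:
        json.dump({"edges": [list(e) for e in inject.edges],
                   "deltas": patient.meta.get("injection_deltas")}, fh,
                  indent=2)
    manifest["artifacts"]["injection_truth.json"] = str(
        outdir / "injection_truth.json")

    anomalies = ref.score_subject(patient, subject_id="patient0")
    restricted = anomalies.restrict_networks(atlas, config.networks_in_scope)
    _write("anomalies.tsv", restricted.to_tsv)
    _write("anomaly_heatmap.png",
           lambda p: render_anomaly_heatmap(restricted, p))

    rx = prescribe_targets(restricted, atlas,
                           max_targets=config.max_targets,
                           depth_max=config.depth_max_mm,
                           min_burden=config.min_burden)
    _write("prescription.json", rx.to_json)

    if rx.targets:
        params = TBSParams()
        session = build_session(rx, params)
        course = build_course(SessionSchedule(), session)
        with open(outdir / "protocol.json", "w") as fh:
            json.dump({"session": session.to_dict(),
                       "course": course.to_dict()}, fh, indent=2)
        manifest["artifacts"]["protocol.json"] = str(
            outdir / "protocol.json")

    with open(outdir / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
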
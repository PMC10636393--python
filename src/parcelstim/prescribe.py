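"""Stimulation-target prescription from an anomaly matrix.

Parcels accumulating many anomalous edges within the implicated networks
become candidate targets. Candidacy requires a cortical parcel within coil
reach (depth <= 30 mm from the scalp); candidates are ranked by total
anomaly burden and capped at three targets. Protocol choice follows the
sign of the burden: predominantly hyperconnected parcels receive cTBS
(inhibitory), predominantly hypoconnected parcels iTBS (excitatory).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas
from .normative import AnomalyMatrix, FLAG_HYPER, FLAG_HYPO

CTBS = "cTBS"
ITBS = "iTBS"


class PrescriptionError(ValueError):
    pass


def anomaly_burden(a: AnomalyMatrix) -> pd.DataFrame:
    """Per-parcel counts of incident flagged edges.

    Returns a DataFrame indexed like the anomaly matrix's parcels with
    columns hyper_count, hypo_count, total_burden. Summed over parcels,
    the totals equal twice the flagged-edge counts (each edge has two
    endpoints).
    """
    hyper = np.zeros(a.n_parcels, dtype=int)
    hypo = np.zeros(a.n_parcels, dtype=int)
    for arr, flag in ((hyper, FLAG_HYPER), (hypo, FLAG_HYPO)):
        sel = a.flags == flag
        np.add.at(arr, a.edge_i[sel], 1)
        np.add.at(arr, a.edge_j[sel], 1)
    return pd.DataFrame({
        "parcel_id": list(a.parcel_ids),
        "hyper_count": hyper,
        "hypo_count": hypo,
        "total_burden": hyper + hypo,
    })


def assign_protocol(hyper_count: int, hypo_count: int) -> str:
    """cTBS when hyperconnections dominate (ties included), else iTBS.

    The tie default follows the cohort's strong cTBS predominance.
    """
    if hyper_count < 0 or hypo_count < 0:
        raise PrescriptionError("counts must be nonnegative")
    if hyper_count == 0 and hypo_count == 0:
        raise PrescriptionError("parcel with no anomalies is not a candidate")
    return CTBS if hyper_count >= hypo_count else ITBS


@dataclass
class PrescribedTarget:
    parcel_id: object
    name: str
    protocol: str
    hyper_count: int
    hypo_count: int
    total_burden: int
    rank: int
    depth_mm: float
    network: str = ""


@dataclass
class TargetPrescription:
    """Ranked stimulation plan (at most three targets)."""

    targets: list
    parameters: dict = field(default_factory=dict)
    reason: str = ""
    patient_id: object = None

    def __len__(self) -> int:
        return len(self.targets)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "targets": [asdict(t) for t in self.targets],
            "parameters": self.parameters,
            "reason": self.reason,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)

    @classmethod
    def from_json(cls, path) -> "TargetPrescription":
        with open(path) as fh:
            d = json.load(fh)
        return cls(targets=[PrescribedTarget(**t) for t in d["targets"]],
                   parameters=d.get("parameters", {}),
                   reason=d.get("reason", ""),
                   patient_id=d.get("patient_id"))

    def report(self) -> str:
        if not self.targets:
            return f"No targets prescribed ({self.reason})."
        lines = ["rank  parcel          protocol  hyper  hypo  depth_mm"]
        for t in self.targets:
            lines.append(
                f"{t.rank:>4}  {str(t.name):<14}  {t.protocol:<8}"
                f"  {t.hyper_count:>5}  {t.hypo_count:>4}  {t.depth_mm:>8.1f}")
        return "\n".join(lines)


def select_targets(burden: pd.DataFrame, atlas: ParcelAtlas,
                   max_targets: int = 3, depth_max: float = 30.0,
                   min_burden: int = 3) -> TargetPrescription:
    """Rank candidate parcels and truncate to the target cap.

    Candidates: cortical parcels with total burden >= min_burden and
    depth <= depth_max (deeper parcels are beyond effective field
    strength). Ranked by total burden descending, ties by hyper count
    descending then parcel_id ascending.
    """
    if len(burden) != atlas.n_parcels:
        raise PrescriptionError("burden table does not match atlas")
    tab = burden.merge(
        atlas.table[["parcel_id", "name", "network", "depth_mm",
                     "subcortical"]],
        on="parcel_id", how="left")
    cand = tab[(~tab["subcortical"].astype(bool))
               & (tab["depth_mm"] <= depth_max)
               & (tab["total_burden"] >= min_burden)]
    params = {"max_targets": max_targets, "depth_max_mm": depth_max,
              "min_burden": min_burden}
    if cand.empty:
        return TargetPrescription(
            targets=[], parameters=params,
            reason="no cortical parcel within depth limit reached "
                   f"the minimum anomaly burden of {min_burden}")
    cand = cand.sort_values(
        by=["total_burden", "hyper_count", "parcel_id"],
        ascending=[False, False, True], kind="mergesort")
    targets = []
    for rank, (_, row) in enumerate(cand.head(max_targets).iterrows(),
                                    start=1):
        targets.append(PrescribedTarget(
            parcel_id=row["parcel_id"], name=row["name"],
            protocol=assign_protocol(int(row["hyper_count"]),
                                     int(row["hypo_count"])),
            hyper_count=int(row["hyper_count"]),
            hypo_count=int(row["hypo_count"]),
            total_burden=int(row["total_burden"]),
            rank=rank, depth_mm=float(row["depth_mm"]),
            network=str(row["network"])))
    return TargetPrescription(targets=targets, parameters=params)


def prescribe_targets(a: AnomalyMatrix, atlas: ParcelAtlas,
                      max_targets: int = 3, depth_max: float = 30.0,
                      min_burden: int = 3) -> TargetPrescription:
    """Convenience: burden computation followed by target selection."""
    rx = select_targets(anomaly_burden(a), atlas, max_targets=max_targets,
                        depth_max=depth_max, min_burden=min_burden)
    rx.patient_id = a.subject_id
    return rx
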
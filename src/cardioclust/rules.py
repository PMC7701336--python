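"""ACDC-style threshold rules for case and cluster pathology labelling.

Per-case rules (all volumes BSA-indexed, mL/m²; ejection fractions as
fractions in (0, 1); thickness in mm; strict inequalities):

* RVA (right-ventricular abnormality): RV EDV > 110 or RV EF < 0.40;
* DCM (dilated cardiomyopathy): LV EDV > 100 and LV EF < 0.40;
* HCM (hypertrophic cardiomyopathy), surrogate rule: maximal myocardial
  thickness > 15 mm with preserved LV EF (>= 0.50).  The reference HCM
  definition also requires an LV mass criterion that the nine-feature table
  cannot express; the rule here is therefore a clearly-flagged surrogate.
* NOR: no rule fires.

The LV EDV is not itself a table column; it is reconstructed from the
identity EDV = ESV / (1 - EF).  Cases with LV EF < 0.40 but EDV <= 100 get an
advisory "low-EF, possible MINF" note (never a label): a myocardial-infarction
call would need segmental wall-motion information.

Cluster labelling: for each cluster the fraction of members satisfying each
pathology rule is computed; a *small* cluster (size <= threshold) is labelled
with the pathology whose satisfaction fraction is maximal, provided that
fraction reaches ``min_frac``; large clusters stay unlabelled under the
default policy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "RVA_RV_EDV_THRESHOLD",
    "RVA_RV_EF_THRESHOLD",
    "DCM_LV_EDV_THRESHOLD",
    "DCM_LV_EF_THRESHOLD",
    "HCM_THICKNESS_THRESHOLD",
    "HCM_NORMAL_EF_THRESHOLD",
    "CaseLabel",
    "ClusterLabeling",
    "classify_case",
    "classify_table",
    "label_clusters",
]

RVA_RV_EDV_THRESHOLD = 110.0  # mL/m², strict >
RVA_RV_EF_THRESHOLD = 0.40   # fraction, strict <
DCM_LV_EDV_THRESHOLD = 100.0  # mL/m², strict >
DCM_LV_EF_THRESHOLD = 0.40   # fraction, strict <
HCM_THICKNESS_THRESHOLD = 15.0  # mm, strict >
HCM_NORMAL_EF_THRESHOLD = 0.50  # fraction, >= ("preserved EF" convention)

PATHOLOGIES = ("DCM", "HCM", "RVA")


class DerivationError(ValueError):
    """Raised when LV EDV cannot be reconstructed (EF_LV = 1)."""


def _get(row: Mapping, key: str) -> Optional[float]:
    try:
        v = row[key]
    except (KeyError, IndexError):
        return None
    if v is None:
        return None
    v = float(v)
    return None if np.isnan(v) else v


@dataclass(frozen=True)
class CaseLabel:
    """Pathology labels of one case; ``is_nor`` iff no label fired.

    ``v_lv_ed`` records the reconstructed LV EDV used by the DCM rule, when
    available.  ``note`` may carry the advisory low-EF remark.
    """

    case_id: str
    labels: FrozenSet[str]
    is_nor: bool
    v_lv_ed: Optional[float] = None
    note: Optional[str] = None


def classify_case(row: Union[Mapping, pd.Series], case_id: Optional[str] = None) -> CaseLabel:
    """Apply the threshold rules to one feature row.

    The row may be a full nine-feature record or a partial one (e.g. only RV
    volume and RV EF); each rule is evaluated only when its inputs are
    present.  LV EDV may be supplied directly as ``V_LV_ED`` or is derived
    from ``V_LV_ES`` and ``EF_LV``.
    """
    if case_id is None:
        cid = _maybe_case_id(row)
    else:
        cid = case_id

    ef_lv = _get(row, "EF_LV")
    ef_rv = _get(row, "EF_RV")
    for name, val in (("EF_LV", ef_lv), ("EF_RV", ef_rv)):
        if val is not None and not (0.0 <= val <= 1.0):
            raise ValueError(
                f"{name}={val} outside [0, 1]; ejection fractions must be "
                "fractions, not percentages"
            )
    v_lv_ed = _get(row, "V_LV_ED")
    v_lv_es = _get(row, "V_LV_ES")
    if v_lv_ed is None and v_lv_es is not None and ef_lv is not None:
        if ef_lv >= 1.0:
            raise DerivationError(f"case {cid}: EF_LV = {ef_lv}; EDV = ESV/(1-EF) undefined")
        v_lv_ed = v_lv_es / (1.0 - ef_lv)
    v_rv_ed = _get(row, "V_RV_ED")
    mt = _get(row, "MT_LVM_ED")

    labels = set()
    evaluable = 0
    if v_rv_ed is not None or ef_rv is not None:
        evaluable += 1
        rva = False
        if v_rv_ed is not None and v_rv_ed > RVA_RV_EDV_THRESHOLD:
            rva = True
        if ef_rv is not None and ef_rv < RVA_RV_EF_THRESHOLD:
            rva = True
        if rva:
            labels.add("RVA")
    if v_lv_ed is not None and ef_lv is not None:
        evaluable += 1
        if v_lv_ed > DCM_LV_EDV_THRESHOLD and ef_lv < DCM_LV_EF_THRESHOLD:
            labels.add("DCM")
    if mt is not None and ef_lv is not None:
        evaluable += 1
        if mt > HCM_THICKNESS_THRESHOLD and ef_lv >= HCM_NORMAL_EF_THRESHOLD:
            labels.add("HCM")

    note = None
    if (
        ef_lv is not None
        and v_lv_ed is not None
        and ef_lv < DCM_LV_EF_THRESHOLD
        and v_lv_ed <= DCM_LV_EDV_THRESHOLD
    ):
        note = "low-EF, possible MINF (not labelled; segmental motion unavailable)"

    return CaseLabel(
        case_id=str(cid),
        labels=frozenset(labels),
        is_nor=(len(labels) == 0),
        v_lv_ed=v_lv_ed,
        note=note,
    )


def _maybe_case_id(row) -> str:
    try:
        return str(row["case_id"])
    except (KeyError, IndexError):
        return ""


def classify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Classify every row; returns case_id, per-pathology booleans, NOR flag."""
    records = []
    for _, row in table.iterrows():
        lab = classify_case(row)
        rec = {"case_id": lab.case_id}
        for p in PATHOLOGIES:
            rec[p] = p in lab.labels
        rec["NOR"] = lab.is_nor
        rec["note"] = lab.note or ""
        records.append(rec)
    return pd.DataFrame(records)


@dataclass
class ClusterInfo:
    cluster: int
    size: int
    is_small: bool
    fractions: Dict[str, float]
    label: Optional[str]  # pathology name or None (unlabelled)

    def to_dict(self) -> dict:
        return {
            "cluster": self.cluster,
            "size": self.size,
            "is_small": self.is_small,
            "fractions": self.fractions,
            "label": self.label if self.label is not None else "UNLABELED",
        }


@dataclass
class ClusterLabeling:
    """Per-cluster pathology labels derived from member rule satisfaction."""

    assignments: np.ndarray
    clusters: List[ClusterInfo]
    small_threshold: int
    min_frac: float

    @property
    def labelled(self) -> Dict[int, str]:
        """cluster index -> pathology, for clusters that received a label."""
        return {c.cluster: c.label for c in self.clusters if c.label is not None}

    def cluster_of(self, pathology: str) -> Optional[ClusterInfo]:
        """The labelled cluster for a pathology, or None; smallest wins ties."""
        hits = [c for c in self.clusters if c.label == pathology]
        if not hits:
            return None
        return min(hits, key=lambda c: (c.size, c.cluster))

    def to_dict(self) -> dict:
        return {
            "small_threshold": self.small_threshold,
            "min_frac": self.min_frac,
            "clusters": [c.to_dict() for c in self.clusters],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def label_clusters(
    assignments: Sequence[int],
    table: pd.DataFrame,
    small_threshold: int,
    min_frac: float = 0.9,
    allow_large: bool = False,
) -> ClusterLabeling:
    """Label clusters by the dominant pathology rule among their members.

    ``assignments`` must cover every row of ``table``.  A cluster is *small*
    when its size is <= ``small_threshold``; only small clusters are eligible
    for a pathology label unless ``allow_large`` is set.  The label is the
    pathology with the highest member-satisfaction fraction, provided it
    reaches ``min_frac``.
    """
    if not (0.0 < min_frac <= 1.0):
        raise ValueError(f"min_frac {min_frac} outside (0, 1]")
    assignments = np.asarray(assignments)
    if len(assignments) != len(table):
        raise ValueError(
            f"assignments cover {len(assignments)} cases, table has {len(table)}"
        )
    case_labels = classify_table(table)
    infos: List[ClusterInfo] = []
    for cl in np.unique(assignments):
        mask = assignments == cl
        size = int(mask.sum())
        is_small = size <= small_threshold
        fractions = {p: float(case_labels.loc[mask, p].mean()) for p in PATHOLOGIES}
        label = None
        if is_small or allow_large:
            best_p = max(PATHOLOGIES, key=lambda p: fractions[p])
            if fractions[best_p] >= min_frac:
                label = best_p
        infos.append(
            ClusterInfo(cluster=int(cl), size=size, is_small=is_small, fractions=fractions, label=label)
        )
    return ClusterLabeling(
        assignments=assignments,
        clusters=infos,
        small_threshold=int(small_threshold),
        min_frac=float(min_frac),
    )
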
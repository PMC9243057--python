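"""Reading and writing session data in the pipeline's on-disk formats.

A session directory holds:

* ``positions.tsv`` — tab-delimited ``timestamp_s  x_cm  y_cm``;
* ``lfp.h5`` (datasets ``mpfc``/``hpc`` with ``sampling_rate`` attributes)
  or ``lfp_mpfc.tsv``/``lfp_hpc.tsv`` with a one-line ``# rate=`` header;
* ``session.yaml`` — rat/condition/epoch, choice-point geometry, trial arms;
* optionally ``truth.tsv`` — the generator's ground-truth sidecar, used
  only by tests.
"""
from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior import Condition, Epoch
from .synthetic import SyntheticSession, TrialTruth
from .trajectory import ChoicePointRegion, PositionTrack, Rect

__all__ = ["write_session", "load_session", "write_cohort", "load_cohort"]


def _rect_to_dict(r: Rect) -> dict:
    return {"x_min": float(r.x_min), "x_max": float(r.x_max),
            "y_min": float(r.y_min), "y_max": float(r.y_max)}


def _rect_from_dict(d: dict) -> Rect:
    return Rect(d["x_min"], d["x_max"], d["y_min"], d["y_max"])


def geometry_to_dict(g: ChoicePointRegion) -> dict:
    return {
        "choice": _rect_to_dict(g.choice),
        "left_arm": _rect_to_dict(g.left_arm),
        "right_arm": _rect_to_dict(g.right_arm),
        "margin": float(g.margin),
    }


def geometry_from_dict(d: dict) -> ChoicePointRegion:
    return ChoicePointRegion(
        choice=_rect_from_dict(d["choice"]),
        left_arm=_rect_from_dict(d["left_arm"]),
        right_arm=_rect_from_dict(d["right_arm"]),
        margin=float(d.get("margin", 0.1)),
    )


def write_session(directory: str | Path, session: SyntheticSession,
                  lfp_format: str = "hdf5", write_truth: bool = True) -> Path:
    """Serialize one session to a directory; returns the directory path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pd.DataFrame({
        "timestamp_s": session.position.timestamps,
        "x_cm": session.position.x,
        "y_cm": session.position.y,
    }).to_csv(directory / "positions.tsv", sep="\t", index=False)

    if lfp_format == "hdf5":
        with h5py.File(directory / "lfp.h5", "w") as f:
            d1 = f.create_dataset("mpfc", data=session.lfp_mpfc)
            d1.attrs["sampling_rate"] = session.lfp_rate
            d2 = f.create_dataset("hpc", data=session.lfp_hpc)
            d2.attrs["sampling_rate"] = session.lfp_rate_hpc
    elif lfp_format == "tsv":
        for name, data, rate in (("mpfc", session.lfp_mpfc, session.lfp_rate),
                                 ("hpc", session.lfp_hpc, session.lfp_rate_hpc)):
            path = directory / f"lfp_{name}.tsv"
            with open(path, "w") as fh:
                fh.write(f"# rate={rate}\n")
                np.savetxt(fh, data, fmt="%.8g")
    else:
        raise ValueError(f"unknown lfp_format {lfp_format!r}")

    meta = {
        "rat_id": session.rat_id,
        "condition": session.condition.value,
        "epoch": session.epoch.value,
        "nominal_rate": float(session.position.nominal_rate),
        "geometry": geometry_to_dict(session.geometry),
        "trials": [{"trial_index": t.trial_index, "arm": t.arm} for t in session.truth],
    }
    with open(directory / "session.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)

    if write_truth:
        pd.DataFrame([{
            "trial_index": t.trial_index, "arm": t.arm, "kind": t.kind,
            "is_vte": t.is_vte, "heading_change": t.heading_change,
            "pass_start_s": t.pass_start_s, "pass_end_s": t.pass_end_s,
            "coupling_strength": t.coupling_strength,
            "coupling_direction": t.coupling_direction,
        } for t in session.truth]).to_csv(directory / "truth.tsv", sep="\t", index=False)
    return directory


def _load_lfp(directory: Path) -> tuple[np.ndarray, np.ndarray, float, float]:
    h5 = directory / "lfp.h5"
    if h5.exists():
        with h5py.File(h5, "r") as f:
            return (f["mpfc"][:], f["hpc"][:],
                    float(f["mpfc"].attrs["sampling_rate"]),
                    float(f["hpc"].attrs["sampling_rate"]))
    traces, rates = [], []
    for name in ("mpfc", "hpc"):
        path = directory / f"lfp_{name}.tsv"
        with open(path) as fh:
            header = fh.readline()
            rate = float(header.split("=", 1)[1])
            traces.append(np.loadtxt(fh))
        rates.append(rate)
    return traces[0], traces[1], rates[0], rates[1]


def load_session(directory: str | Path) -> SyntheticSession:
    """Load a session directory back into the in-memory container.

    The ground-truth sidecar (if present) is attached; otherwise the
    truth list holds only the trial arms from the session metadata.
    """
    directory = Path(directory)
    with open(directory / "session.yaml") as fh:
        meta = yaml.safe_load(fh)
    pos = pd.read_csv(directory / "positions.tsv", sep="\t")
    track = PositionTrack(pos["timestamp_s"].to_numpy(), pos["x_cm"].to_numpy(),
                          pos["y_cm"].to_numpy(), nominal_rate=meta["nominal_rate"])
    mpfc, hpc, rate, rate_hpc = _load_lfp(directory)

    truth_path = directory / "truth.tsv"
    if truth_path.exists():
        tdf = pd.read_csv(truth_path, sep="\t")
        truth = [TrialTruth(int(r.trial_index), str(r.arm), str(r.kind), bool(r.is_vte),
                            float(r.heading_change), float(r.pass_start_s),
                            float(r.pass_end_s), float(r.coupling_strength),
                            str(r.coupling_direction))
                 for r in tdf.itertuples()]
    else:
        truth = [TrialTruth(t["trial_index"], t["arm"], "unknown", False,
                            np.nan, np.nan, np.nan, np.nan, "unknown")
                 for t in meta["trials"]]
    return SyntheticSession(
        rat_id=meta["rat_id"], condition=Condition(meta["condition"]),
        epoch=Epoch(meta["epoch"]), position=track, lfp_mpfc=mpfc, lfp_hpc=hpc,
        lfp_rate=rate, lfp_rate_hpc=rate_hpc,
        geometry=geometry_from_dict(meta["geometry"]), truth=truth,
    )


def write_cohort(directory: str | Path, sessions: list[SyntheticSession],
                 lfp_format: str = "hdf5") -> Path:
    """Write all sessions plus a manifest; returns the cohort directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for s in sessions:
        name = f"{s.rat_id}_{s.condition.value}_{s.epoch.value}"
        write_session(directory / name, s, lfp_format=lfp_format)
        manifest.append({"rat_id": s.rat_id, "condition": s.condition.value,
                         "epoch": s.epoch.value, "path": name})
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"sessions": manifest}, fh, sort_keys=False)
    return directory


def load_cohort(directory: str | Path) -> list[SyntheticSession]:
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    missing = [e["path"] for e in manifest["sessions"]
               if not (directory / e["path"] / "session.yaml").exists()]
    if missing:
        raise FileNotFoundError(f"manifest references missing sessions: {missing}")
    return [load_session(directory / e["path"]) for e in manifest["sessions"]]
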
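"""End-to-end experiment orchestration.

Builds per-treatment parameter sets (either read verbatim from the packaged
tables or derived from the base set through the P-response functions), runs
stochastic ensembles of plant simulations coupled to the hydraulic solver,
and summarizes the root-system conductance K_rs per treatment over time —
the protocol behind a four-treatment, 28-day, n-replicate experiment with
K_rs evaluated at 7, 14, 21 and 28 days after sowing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .architecture import (PlantNetwork, PlantParams, Segment,
                           build_plant_params, simulate_plant, summarize)
from .hydraulics import HydraulicProfile, krs_time_series
from .presponse import PResponseModel, apply_response, fit_response_model
from .tables import (SOIL_P_LEVELS, TREATMENTS, data_path, load_parameter_table)

__all__ = ["EnsembleResult", "build_treatment", "run_ensemble",
           "summarize_experiment", "export_segments", "import_segments",
           "table_checksums", "extract_from_rsml_series"]

DEFAULT_TIMES = (7.0, 14.0, 21.0, 28.0)


def table_checksums() -> dict:
    """SHA-256 of the packaged parameter files, for report provenance."""
    out = {}
    for name in ("root_system_parameters.csv", "root_type_parameters.csv",
                 "shoot_parameters.csv", "hydraulic_profiles_synthetic.csv"):
        out[name] = hashlib.sha256(data_path(name).read_bytes()).hexdigest()
    return out


def _default_dry_matter() -> dict:
    dm = pd.read_csv(data_path("dry_matter_synthetic.csv"), comment="#")
    return dict(zip(dm["treatment"], dm["dm_plant_g"]))


def build_treatment(treatment: str, mode: str = "tabulated",
                    model: Optional[PResponseModel] = None,
                    dm_plant: Optional[float] = None) -> PlantParams:
    """Plant parameters for one treatment.

    ``tabulated`` reads the packaged per-treatment tables verbatim;
    ``response-driven`` starts from the "general" base set and modifies only
    the identified response parameters (axial radii, crown elongation, leaf
    elongation) through the fitted P-response functions at that treatment's
    soil-P level.
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    if mode == "tabulated":
        return build_plant_params(load_parameter_table(treatment))
    if mode == "response-driven":
        base = load_parameter_table("general")
        model = model or fit_response_model()
        dm = dm_plant if dm_plant is not None else _default_dry_matter()[treatment]
        table = apply_response(base, SOIL_P_LEVELS[treatment], dm, model)
        table.treatment = treatment
        return build_plant_params(table)
    raise ValueError(f"unknown mode {mode!r}; use 'tabulated' or 'response-driven'")


@dataclass
class EnsembleResult:
    """Per-seed K_rs series and architecture summaries for one treatment."""

    treatment: str
    seeds: list
    times: np.ndarray
    krs: np.ndarray  # (n_seeds, n_times)
    summaries: list = field(default_factory=list)  # per-seed summarize() dicts
    provenance: dict = field(default_factory=dict)

    def mean(self) -> np.ndarray:
        return self.krs.mean(axis=0)

    def sd(self) -> np.ndarray:
        return self.krs.std(axis=0, ddof=1) if len(self.seeds) > 1 \
            else np.zeros(self.krs.shape[1])

    def sem(self) -> np.ndarray:
        return self.sd() / np.sqrt(len(self.seeds))

    def total_volume(self) -> np.ndarray:
        """Per-seed total root volume (cm³) at the final time."""
        return np.array([s["roots-total"]["volume"] for s in self.summaries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "treatment": self.treatment,
            "time_d": np.tile(self.times, len(self.seeds)),
            "seed": np.repeat(self.seeds, len(self.times)),
            "krs_cm2_per_d": self.krs.ravel(),
        })


def run_ensemble(params: PlantParams, n: int, base_seed: int,
                 times=DEFAULT_TIMES,
                 profile: Optional[HydraulicProfile] = None) -> EnsembleResult:
    """Run ``n`` independent plant simulations and solve K_rs at each time.

    Replicate seeds are ``base_seed + index`` so runs are exactly
    reproducible and individually replayable.  All stochastic organ
    parameters are redrawn per replicate.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    profile = profile or HydraulicProfile.default()
    times = np.asarray(times, dtype=float)
    t_end = float(times.max())
    seeds = [int(base_seed) + i for i in range(n)]
    krs = np.empty((n, times.size))
    summaries = []
    for i, seed in enumerate(seeds):
        try:
            net = simulate_plant(params, t_end, rng_seed=seed)
            series = krs_time_series(net, profile, times)
        except Exception as exc:
            raise RuntimeError(f"replicate with seed {seed} failed: {exc}") from exc
        krs[i] = [k for _, k in series]
        summaries.append(summarize(net))
    prov = {"package_version": __version__, "treatment": params.treatment,
            "base_seed": int(base_seed), "n": n, "times": times.tolist(),
            "table_checksums": table_checksums()}
    return EnsembleResult(treatment=params.treatment, seeds=seeds, times=times,
                          krs=krs, summaries=summaries, provenance=prov)


def summarize_experiment(results: dict, welch: bool = False) -> pd.DataFrame:
    """Mean ± s.d. K_rs per treatment per time (long-format table).

    With ``welch=True``, appends descriptive Welch t-tests of the last
    treatment against each other at every time point (no multiplicity
    control — descriptive only).
    """
    rows = []
    for label, res in results.items():
        for j, t in enumerate(res.times):
            rows.append({"treatment": label, "time_d": float(t),
                         "krs_mean": res.mean()[j], "krs_sd": res.sd()[j],
                         "krs_sem": res.sem()[j], "n": len(res.seeds)})
    table = pd.DataFrame(rows)
    if welch and len(results) >= 2:
        from scipy import stats
        labels = list(results)
        ref = labels[-1]
        tests = []
        for other in labels[:-1]:
            for j, t in enumerate(results[ref].times):
                tt = stats.ttest_ind(results[ref].krs[:, j],
                                     results[other].krs[:, j], equal_var=False)
                tests.append({"comparison": f"{ref} vs {other}",
                              "time_d": float(t), "t": tt.statistic,
                              "p_descriptive": tt.pvalue})
        table.attrs["welch_tests"] = pd.DataFrame(tests)
    return table


# -- segment-table interchange ---------------------------------------------

def export_segments(net: PlantNetwork, path) -> None:
    """Write the network as a delimited per-segment table."""
    nodes = net.node_array()
    rows = []
    for s in net.segments:
        px, py, pz = nodes[s.prox]
        dx_, dy, dz = nodes[s.dist]
        rows.append({"id": s.id, "parent": s.parent, "organ": s.organ_id,
                     "type": s.organ_type,
                     "prox_x": px, "prox_y": py, "prox_z": pz,
                     "dist_x": dx_, "dist_y": dy, "dist_z": dz,
                     "radius": s.radius, "creation_time": s.creation_time})
    pd.DataFrame(rows).to_csv(path, index=False)


def import_segments(path) -> PlantNetwork:
    """Rebuild a network from a per-segment table written by export_segments."""
    df = pd.read_csv(path)
    t_end = float(df["creation_time"].max()) if len(df) else 0.0
    net = PlantNetwork(t_end)
    node_ids: dict[tuple, int] = {tuple(np.round([0.0, 0.0, 0.0], 9)): 0}

    def node_of(x, y, z):
        key = tuple(np.round([x, y, z], 9))
        if key not in node_ids:
            node_ids[key] = net.add_node([x, y, z])
        return node_ids[key]

    from .architecture import OrganInfo
    for _, row in df.iterrows():
        prox = node_of(row["prox_x"], row["prox_y"], row["prox_z"])
        dist = node_of(row["dist_x"], row["dist_y"], row["dist_z"])
        net.add_segment(int(row["organ"]), row["type"], prox, dist,
                        float(row["radius"]), float(row["creation_time"]),
                        int(row["parent"]))
        oid = int(row["organ"])
        if oid not in net.organs:
            net.organs[oid] = OrganInfo(oid, row["type"],
                                        float(row["creation_time"]),
                                        1.0, 1.0, float(row["radius"]), -1)
    return net


# -- RSML parameter extraction ----------------------------------------------

def extract_from_rsml_series(files_with_days: list) -> dict:
    """Extract growth and radius statistics from an RSML time series.

    ``files_with_days`` is a list of (path, day) pairs for one plant.  Roots
    are matched across days by id; per root, the arc-length series is fitted
    with the fixed-``l_max`` elongation model (139 cm for axial types, the
    packaged general table's lateral maxima otherwise).  Returns per-type
    mean (and s.d.) of the fitted ``r`` and of the traced radii.
    """
    from .architecture import AXIAL_L_MAX
    from .growth import fit_elongation
    from .rsml import read_rsml

    general = load_parameter_table("general")
    lmax_by_type = {"primary": AXIAL_L_MAX, "seminal": AXIAL_L_MAX,
                    "crown": AXIAL_L_MAX,
                    "l-lateral": general.get("l-lateral", "l_max")[0],
                    "s-lateral": general.get("s-lateral", "l_max")[0]}

    lengths: dict[str, list] = {}
    types: dict[str, str] = {}
    radii: dict[str, list] = {}
    emergence: dict[str, float] = {}
    for path, day in sorted(files_with_days, key=lambda fd: fd[1]):
        for root in read_rsml(path):
            lengths.setdefault(root.id, []).append((float(day), root.length))
            types[root.id] = root.type_label
            radii.setdefault(root.id, []).extend(root.radii.tolist())
            if root.creation_times is not None and root.id not in emergence:
                emergence[root.id] = float(root.creation_times[0])

    fits: dict[str, list] = {}
    radius_stats: dict[str, list] = {}
    for rid, series in lengths.items():
        rtype = types[rid]
        radius_stats.setdefault(rtype, []).append(float(np.mean(radii[rid])))
        lmax = lmax_by_type.get(rtype)
        if lmax is None or len(series) < 2:
            continue
        arr = np.asarray(series)
        arr = arr[arr[:, 1] < lmax * (1 - 1e-9)]
        if len(arr) < 2 or np.all(arr[:, 1] == 0):
            continue
        # organ emergence from traced creation times when the files carry
        # them; otherwise assume the root appeared one day before it was
        # first seen (daily-imaging convention)
        t0 = emergence.get(rid, arr[0, 0] - 1.0)
        arr = arr[arr[:, 0] > t0]
        if len(arr) < 2:
            continue
        arr = np.column_stack([arr[:, 0] - t0, np.maximum.accumulate(arr[:, 1])])
        try:
            fits.setdefault(rtype, []).append(fit_elongation(arr, lmax).r_hat)
        except ValueError:
            continue

    out = {}
    for rtype in set(list(fits) + list(radius_stats)):
        entry = {}
        if rtype in fits:
            entry["r_mean"] = float(np.mean(fits[rtype]))
            entry["r_sd"] = float(np.std(fits[rtype], ddof=1)) \
                if len(fits[rtype]) > 1 else 0.0
            entry["n_roots_fitted"] = len(fits[rtype])
        if rtype in radius_stats:
            entry["a_mean"] = float(np.mean(radius_stats[rtype]))
            entry["a_sd"] = float(np.std(radius_stats[rtype], ddof=1)) \
                if len(radius_stats[rtype]) > 1 else 0.0
        out[rtype] = entry
    out["_emergence_source"] = ("rsml_creation_times" if emergence
                                else "first_visible_day_minus_one")
    return out


def write_report(results: dict, out_dir, config: Optional[dict] = None) -> Path:
    """Write the experiment summary (CSV) and a provenance JSON report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = summarize_experiment(results)
    table.to_csv(out_dir / "krs_summary.csv", index=False)
    report = {
        "package_version": __version__,
        "config": config or {},
        "table_checksums": table_checksums(),
        "treatments": {label: res.provenance for label, res in results.items()},
        "krs_mean_final": {label: float(res.mean()[-1])
                           for label, res in results.items()},
    }
    path = out_dir / "report.json"
    path.write_text(json.dumps(report, indent=2))
    return path
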
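"""Machine-readable reports: matrix tables, summaries, run manifests.

Every export carries a manifest that pins all parameters and seeds; a
run re-executed from its manifest reproduces the tables bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import ContactMatrix, assortativity_q, average_matrix
from .scenarios import ScenarioResult, reduction

__all__ = [
    "RunManifest",
    "report_scenario_comparison",
    "export_matrices",
    "read_matrix",
]


def _canonical(params: dict) -> str:
    return json.dumps(params, sort_keys=True, default=str)


@dataclass
class RunManifest:
    """Provenance record that fully determines a run."""

    params: dict
    seed: int | None = None
    code_version: str = ""
    extrapolated: bool = False
    created: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    config_hash: str = ""

    def __post_init__(self) -> None:
        if not self.code_version:
            from . import __version__

            self.code_version = __version__
        if not self.config_hash:
            self.config_hash = hashlib.sha256(_canonical(self.params).encode()).hexdigest()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def report_scenario_comparison(
    baseline: ScenarioResult,
    scenario: ScenarioResult,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-age-bin and overall contact reductions of a scenario vs baseline.

    A bin's contact rate is the row sum of the per-capita matrix (mean
    contacts per person of that bin).  The per-bin table holds the
    fractional decrease ``1 - scenario/baseline`` per area and overall
    (NaN where the baseline row is zero); the summary table reports the
    area-level decrease together with the equivalent increase
    ``scenario/baseline - 1``, since a negative decrease reads more
    naturally as an increase.
    """
    if set(baseline.per_location) != set(scenario.per_location):
        raise ValueError("baseline and scenario cover different activity areas")
    labels = next(iter(baseline.per_location.values()))[0].labels
    per_bin = {}
    rows_summary = []
    names = list(baseline.per_location)
    for name in names + ["overall"]:
        if name == "overall":
            b_m, s_m = baseline.overall_m, scenario.overall_m
            b_mean, s_mean = baseline.mean_contacts(), scenario.mean_contacts()
        else:
            b_m, s_m = baseline.location_m[name], scenario.location_m[name]
            b_mean, s_mean = baseline.mean_contacts(name), scenario.mean_contacts(name)
        b_rows, s_rows = b_m.sum(axis=1), s_m.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            red = np.where(b_rows > 0, 1.0 - s_rows / np.where(b_rows > 0, b_rows, 1.0), np.nan)
        per_bin[name] = red
        dec = reduction(b_mean, s_mean) if b_mean > 0 else np.nan
        rows_summary.append(
            {
                "location": name,
                "baseline_mean_contacts": b_mean,
                "scenario_mean_contacts": s_mean,
                "decrease": dec,
                "increase": -dec if not np.isnan(dec) else np.nan,
            }
        )
    per_bin_df = pd.DataFrame(per_bin, index=list(labels))
    per_bin_df.index.name = "age_bin"
    return per_bin_df, pd.DataFrame(rows_summary).set_index("location")


def export_matrices(
    matrices: dict[str, ContactMatrix],
    path: str | Path,
    manifest: RunManifest | None = None,
) -> dict[str, Path]:
    """Write per-area C and m tables, the area average, Q indices, manifest.

    Tables are CSV with age-bin labels as headers; the summary JSON holds
    total contacts, mean contacts per person and Q per area plus the
    average matrix's Q.  Files round-trip losslessly through
    :func:`read_matrix`.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    summary: dict[str, dict] = {}
    for name, cm in matrices.items():
        labels = list(cm.labels)
        for kind, arr in (("C", cm.C), ("m", cm.m)):
            f = out / f"{name}_{kind}.csv"
            pd.DataFrame(arr, index=labels, columns=labels).to_csv(f)
            written[f"{name}_{kind}"] = f
        f = out / f"{name}_n.csv"
        pd.Series(cm.n, index=labels, name="n").to_csv(f)
        written[f"{name}_n"] = f
        summary[name] = {
            "total_contacts": cm.total_contacts,
            "mean_contacts_per_person": cm.mean_contacts_per_person,
            "Q": assortativity_q(cm.m) if cm.m.any() else None,
            "extrapolated": cm.extrapolated,
        }
    if len(matrices) > 1:
        avg = average_matrix(list(matrices.values()))
        labels = list(next(iter(matrices.values())).labels)
        f = out / "average_m.csv"
        pd.DataFrame(avg, index=labels, columns=labels).to_csv(f)
        written["average_m"] = f
        summary["average"] = {"Q": assortativity_q(avg) if avg.any() else None}
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    written["summary"] = out / "summary.json"
    if manifest is not None:
        manifest.to_json(out / "manifest.json")
        written["manifest"] = out / "manifest.json"
    return written


def read_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a matrix table written by :func:`export_matrices`."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return list(df.index.astype(str)), df.to_numpy(dtype=float)
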
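"""Reading and writing traces, schemes and reports.

Traces travel as a long-format CSV (trace_id, frame, time_s, intensity) with a
companion JSON metadata file holding each trace's condition (and, for
synthetic data, the generating scheme).  Ground-truth jump paths are an
optional CSV (trace_id, jump_time_s, state).  Schemes and configs are YAML or
JSON, chosen by file extension.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scheme import Condition, KineticScheme, RateSpec
from .simulate import IntensityTrace, StatePath

__all__ = [
    "write_traces",
    "read_traces",
    "write_truth",
    "read_truth",
    "scheme_to_dict",
    "scheme_from_dict",
    "read_scheme",
    "write_scheme",
    "write_report",
]

TRACE_COLUMNS = ["trace_id", "frame", "time_s", "intensity"]


def write_traces(
    traces: list[IntensityTrace],
    csv_path,
    meta_path,
    scheme: KineticScheme | None = None,
) -> None:
    rows = []
    for tr in traces:
        rows.append(
            pd.DataFrame(
                {
                    "trace_id": tr.trace_id,
                    "frame": np.arange(len(tr)),
                    "time_s": tr.times,
                    "intensity": tr.intensities,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "traces": {
            tr.trace_id: {
                "catalyst_label": tr.condition.catalyst_label,
                "catalyst_conc_mM": tr.condition.catalyst_conc_mM,
                "diene_conc_mM": tr.condition.diene_conc_mM,
            }
            for tr in traces
        }
    }
    if scheme is not None:
        meta["scheme"] = scheme_to_dict(scheme)
    Path(meta_path).write_text(json.dumps(meta, indent=1))


def read_traces(csv_path, meta_path=None) -> list[IntensityTrace]:
    df = pd.read_csv(csv_path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table is missing column(s): {', '.join(missing)}")
    bad = df.index[~np.isfinite(df["intensity"].to_numpy(dtype=float))]
    if len(bad):
        # +2: header line plus 1-based numbering, to match what an editor shows.
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(f"non-finite intensity values at CSV line(s) {lines}")
    meta = {}
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text()).get("traces", {})
    traces = []
    for tid, sub in df.groupby("trace_id", sort=False):
        sub = sub.sort_values("frame")
        m = meta.get(str(tid), {})
        cond = Condition(
            catalyst_label=m.get("catalyst_label", "cat"),
            catalyst_conc_mM=float(m.get("catalyst_conc_mM", 0.0)),
            diene_conc_mM=float(m.get("diene_conc_mM", 0.0)),
        )
        traces.append(
            IntensityTrace(
                trace_id=str(tid),
                condition=cond,
                times=sub["time_s"].to_numpy(dtype=float),
                intensities=sub["intensity"].to_numpy(dtype=float),
            )
        )
    if not traces:
        raise ValueError(f"no traces found in {csv_path}")
    return traces


def write_truth(traces: list[IntensityTrace], path) -> None:
    rows = []
    for tr in traces:
        if tr.truth is None:
            continue
        for t, s in zip(tr.truth.jump_times, tr.truth.states):
            rows.append({"trace_id": tr.trace_id, "jump_time_s": t, "state": s})
    pd.DataFrame(rows, columns=["trace_id", "jump_time_s", "state"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_truth(path) -> dict[str, StatePath]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for tid, sub in df.groupby("trace_id", sort=False):
        out[str(tid)] = StatePath(
            sub["jump_time_s"].to_numpy(dtype=float), list(sub["state"])
        )
    return out


# ---------------------------------------------------------------------------
# schemes


def scheme_to_dict(scheme: KineticScheme) -> dict:
    return {
        "states": list(scheme.states),
        "absorbing": sorted(scheme.absorbing & set(scheme.states)),
        "rates": [
            {
                "from": src,
                "to": dst,
                "value": spec.value,
                "order": spec.order,
                "coupled_species": spec.coupled_species,
            }
            for (src, dst), spec in sorted(scheme.rates.items())
        ],
    }


def scheme_from_dict(d: dict) -> KineticScheme:
    rates = {}
    for r in d.get("rates", []):
        rates[(r["from"], r["to"])] = RateSpec(
            value=float(r["value"]),
            order=r.get("order", "unimolecular"),
            coupled_species=r.get("coupled_species", "none"),
        )
    absorbing = set(d.get("absorbing", [])) | {"P", "BLEACHED"}
    return KineticScheme(
        states=tuple(d["states"]), rates=rates, absorbing=frozenset(absorbing)
    )


def _load_structured(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def read_scheme(path) -> KineticScheme:
    return scheme_from_dict(_load_structured(path))


def write_scheme(scheme: KineticScheme, path) -> None:
    path = Path(path)
    d = scheme_to_dict(scheme)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=1))


# ---------------------------------------------------------------------------
# reports


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=1))
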
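"""Plain-text columnar I/O for runs, matrices and design tables.

Every writer stamps a header of ``# key=value`` lines recording the tool
version, config hash and seed, so reruns are auditable and diffable.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd

from . import __version__
from .masses_digestion import FragmentAnnotation
from .synthetic_data import ChromatogramSet

__all__ = [
    "header_lines",
    "write_run",
    "read_run",
    "write_matrix",
    "read_matrix",
    "write_design",
    "read_design",
    "write_table",
    "read_table",
]


def header_lines(config=None, seed=None, **extra) -> list[str]:
    from .config import RunConfig, config_hash

    cfg = config or RunConfig()
    lines = [f"ubidia_version={__version__}", f"config_hash={config_hash(cfg)}"]
    if seed is not None:
        lines.append(f"seed={seed}")
    lines += [f"{k}={v}" for k, v in extra.items()]
    return lines


def _write_header(fh, lines) -> None:
    for line in lines:
        fh.write(f"# {line}\n")


def _skip_header(fh) -> dict[str, str]:
    meta = {}
    pos = fh.tell()
    while True:
        line = fh.readline()
        if not line.startswith("#"):
            fh.seek(pos)
            break
        body = line[1:].strip()
        if "=" in body:
            k, v = body.split("=", 1)
            meta[k] = v
        pos = fh.tell()
    return meta


# ---------------------------------------------------------------------------
# DIA run serialization: one row per fragment trace (plus an MS1 row)
# ---------------------------------------------------------------------------

def write_run(path, chromatograms: dict[str, ChromatogramSet],
              pairs: dict[str, str], header=()) -> None:
    with open(path, "w", newline="") as fh:
        _write_header(fh, header)
        first = next(iter(chromatograms.values()))
        fh.write("# rt_grid=" + ",".join(f"{t:.4f}" for t in first.rt) + "\n")
        w = csv.writer(fh, delimiter="\t")
        w.writerow([
            "precursor_id", "decoy", "paired_target", "fragment_id", "series",
            "index", "charge", "mz", "contains_mod_site",
            "contains_other_candidate_site", "trace",
        ])
        decoy_of = {d: t for t, d in pairs.items()}
        for pid in sorted(chromatograms):
            cs = chromatograms[pid]
            decoy = pid in decoy_of
            paired = decoy_of.get(pid, "")
            for ann, trace in zip(cs.fragments, cs.fragment_traces):
                w.writerow([
                    pid, int(decoy), paired, ann.fragment_id, ann.series,
                    ann.index, ann.charge, f"{ann.mz:.6f}",
                    int(ann.contains_mod_site),
                    int(ann.contains_other_candidate_site),
                    ",".join(f"{v:.4f}" for v in trace),
                ])
            w.writerow([pid, int(decoy), paired, "MS1", "", "", "", "", "", "",
                        ",".join(f"{v:.4f}" for v in cs.ms1_trace)])


def read_run(path) -> tuple[dict[str, ChromatogramSet], dict[str, str], dict]:
    """Returns (chromatograms, target->decoy pairs, header metadata)."""
    with open(path) as fh:
        meta = _skip_header(fh)
        rt = np.array([float(v) for v in meta["rt_grid"].split(",")])
        reader = csv.DictReader(fh, delimiter="\t")
        frags: dict[str, list] = {}
        traces: dict[str, list] = {}
        ms1: dict[str, np.ndarray] = {}
        pairs: dict[str, str] = {}
        for row in reader:
            pid = row["precursor_id"]
            if row["paired_target"]:
                pairs[row["paired_target"]] = pid
            vec = np.array([float(v) for v in row["trace"].split(",")])
            if row["fragment_id"] == "MS1":
                ms1[pid] = vec
                continue
            ann = FragmentAnnotation(
                series=row["series"],
                index=int(row["index"]),
                charge=int(row["charge"]),
                mz=float(row["mz"]),
                contains_mod_site=bool(int(row["contains_mod_site"])),
                contains_other_candidate_site=bool(
                    int(row["contains_other_candidate_site"])
                ),
            )
            frags.setdefault(pid, []).append(ann)
            traces.setdefault(pid, []).append(vec)
    chroms = {
        pid: ChromatogramSet(
            rt=rt,
            fragments=tuple(frags[pid]),
            fragment_traces=np.array(traces[pid]),
            ms1_trace=ms1[pid],
        )
        for pid in frags
    }
    return chroms, pairs, meta


# ---------------------------------------------------------------------------
# Matrices and tables
# ---------------------------------------------------------------------------

def write_matrix(path, data: pd.DataFrame, header=(), feature_col="feature") -> None:
    """Feature-id first column; missing values as empty fields."""
    with open(path, "w", newline="") as fh:
        _write_header(fh, header)
        out = data.copy()
        out.insert(0, feature_col, data.index)
        out.to_csv(fh, sep="\t", index=False, na_rep="")


def read_matrix(path, feature_col="feature") -> tuple[pd.DataFrame, dict]:
    with open(path) as fh:
        meta = _skip_header(fh)
        df = pd.read_csv(fh, sep="\t")
    df = df.set_index(feature_col)
    return df, meta


def write_design(path, design: pd.DataFrame, header=()) -> None:
    with open(path, "w", newline="") as fh:
        _write_header(fh, header)
        out = design.copy()
        out.insert(0, "sample", design.index)
        out.to_csv(fh, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    with open(path) as fh:
        _skip_header(fh)
        df = pd.read_csv(fh, sep="\t")
    return df.set_index("sample")


def write_table(path, df: pd.DataFrame, header=()) -> None:
    with open(path, "w", newline="") as fh:
        _write_header(fh, header)
        df.to_csv(fh, sep="\t", index=False, na_rep="")


def read_table(path) -> tuple[pd.DataFrame, dict]:
    with open(path) as fh:
        meta = _skip_header(fh)
        df = pd.read_csv(fh, sep="\t")
    return df, meta
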
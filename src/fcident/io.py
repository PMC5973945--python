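"""Plain-text and HDF5 I/O for cohorts, bases and result tables.

Conventions: FC matrices and time series are TSV with a header row of region
labels; the cohort manifest is CSV with columns subject,visit,condition,path;
the node partition is CSV region,network; behavioral scores are CSV
subject,score.  Floating-point outputs are written at 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .decomposition import ConnectomePCA
from .fc import CohortStack, FCMatrix, TimeSeries, stack_cohort
from .synthetic import CohortTruth

__all__ = [
    "read_fc_tsv",
    "write_fc_tsv",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_manifest",
    "read_partition",
    "read_scores",
    "load_cohort",
    "write_cohort",
    "write_basis",
    "read_basis",
    "write_table",
]

FLOAT_FMT = "%.12g"


def write_fc_tsv(fc: FCMatrix, path: str | Path) -> None:
    header = "\t".join(fc.region_labels)
    np.savetxt(path, fc.values, fmt=FLOAT_FMT, delimiter="\t", header=header, comments="")


def read_fc_tsv(path: str | Path) -> FCMatrix:
    df = pd.read_csv(path, sep="\t")
    return FCMatrix(df.to_numpy(dtype=float), region_labels=[str(c) for c in df.columns])


def write_timeseries_tsv(ts: TimeSeries, path: str | Path) -> None:
    # rows = frames, columns = regions (transposed for a conventional table)
    header = "\t".join(ts.region_labels)
    np.savetxt(path, ts.values.T, fmt=FLOAT_FMT, delimiter="\t", header=header, comments="")


def read_timeseries_tsv(path: str | Path) -> TimeSeries:
    df = pd.read_csv(path, sep="\t")
    return TimeSeries(df.to_numpy(dtype=float).T, region_labels=[str(c) for c in df.columns])


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject" not in df.columns and "subject_id" in df.columns:
        df = df.rename(columns={"subject_id": "subject"})
    return df


def read_partition(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    region = cols.get("region", cols.get("region_label"))
    network = cols.get("network", cols.get("network_id"))
    if region is None or network is None:
        raise ValueError("partition CSV needs columns region,network")
    return df.rename(columns={region: "region", network: "network"})[["region", "network"]]


def read_scores(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    if "subject" not in df.columns and "subject_id" in df.columns:
        df = df.rename(columns={"subject_id": "subject"})
    if not {"subject", "score"}.issubset(df.columns):
        raise ValueError("behavior CSV needs columns subject,score")
    return df.set_index("subject")["score"].astype(float)


def load_cohort(manifest_path: str | Path, partition_path: str | Path | None = None) -> CohortStack:
    """Read a manifest CSV and the FC matrices it points to into a stack."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    matrices = {}
    for p in manifest["path"].unique():
        fp = Path(p)
        matrices[p] = read_fc_tsv(fp if fp.is_absolute() else base / fp)
    network_ids = None
    if partition_path is not None:
        part = read_partition(partition_path)
        labels = next(iter(matrices.values())).region_labels
        lookup = dict(zip(part["region"].astype(str), part["network"].astype(str)))
        missing = [r for r in labels if r not in lookup]
        if missing:
            raise ValueError(f"partition missing regions: {missing}")
        network_ids = [lookup[r] for r in labels]
    return stack_cohort(manifest, matrices, network_ids=network_ids)


def write_cohort(
    stack: CohortStack, out_dir: str | Path, truth: CohortTruth | None = None
) -> Path:
    """Write per-session FC TSVs, a manifest CSV and an optional truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for k in range(stack.n_sessions):
        meta = stack.sessions.iloc[k]
        name = f"fc_{meta['subject']}_{meta['condition']}_{meta['visit']}.tsv"
        write_fc_tsv(stack.column_fc(k), out / name)
        rows.append(
            {
                "subject": meta["subject"],
                "visit": meta["visit"],
                "condition": meta["condition"],
                "path": name,
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    if truth is not None:
        payload = truth.summary()
        payload["spec"] = vars(truth.spec)
        payload["group"] = truth.group.tolist()
        payload["fingerprints"] = truth.fingerprints.tolist()
        (out / "truth.json").write_text(json.dumps(payload))
    return out / "manifest.csv"


def write_basis(basis: ConnectomePCA, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("modes", data=basis.modes_)
        h5.create_dataset("scores", data=basis.scores_)
        h5.create_dataset("means", data=basis.column_means_)
        h5.create_dataset("explained_variance", data=basis.explained_variance_ratio_)


def read_basis(path: str | Path) -> ConnectomePCA:
    basis = ConnectomePCA()
    with h5py.File(path, "r") as h5:
        basis.modes_ = h5["modes"][()]
        basis.scores_ = h5["scores"][()]
        basis.column_means_ = h5["means"][()]
        basis.explained_variance_ratio_ = h5["explained_variance"][()]
    basis.n_edges_, basis.n_components_ = basis.modes_.shape
    basis.n_sessions_ = basis.scores_.shape[1]
    return basis


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)
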
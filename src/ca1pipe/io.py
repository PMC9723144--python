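"""Session container I/O (HDF5) and tabular result export (TSV + manifest)."""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .containers import Session

log = logging.getLogger("ca1pipe")


def save_session(session: Session, path) -> Path:
    """Write one session to an HDF5 container (datasets lfp/<role>,
    ca_traces, position, optional emg; rates and metadata as attributes)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group("lfp")
        for role, x in session.lfp.items():
            g.create_dataset(role, data=np.asarray(x, dtype=np.float64))
        f.create_dataset("ca_traces", data=np.asarray(session.ca_traces, dtype=np.float64))
        f.create_dataset("position", data=np.asarray(session.position, dtype=np.float64))
        if session.emg is not None:
            f.create_dataset("emg", data=np.asarray(session.emg, dtype=np.float64))
        f.attrs["fs_lfp"] = session.fs_lfp
        f.attrs["fs_ca"] = session.fs_ca
        f.attrs["track_length"] = session.track_length
        f.attrs["meta"] = json.dumps(session.meta)
    return path


def load_session(path, config: AnalysisConfig | None = None) -> Session:
    """Read and validate a session container.

    Sampling rates stored in the file win over config defaults; a mismatch
    with an explicitly provided config is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        lfp = {role: f["lfp"][role][()] for role in f["lfp"]}
        ses = Session(
            lfp=lfp,
            ca_traces=f["ca_traces"][()],
            position=f["position"][()],
            track_length=float(f.attrs["track_length"]),
            fs_lfp=float(f.attrs["fs_lfp"]),
            fs_ca=float(f.attrs["fs_ca"]),
            meta=json.loads(f.attrs.get("meta", "{}")),
            emg=f["emg"][()] if "emg" in f else None,
        )
    if config is not None:
        if ses.fs_lfp != config.fs_lfp or ses.fs_ca != config.fs_ca:
            raise ValueError("sampling rates in container do not match config")
    ses.validate()
    log.info("loaded session %s: %d LFP channels (%s), %d cells, %.1f s",
             path.name, len(ses.lfp), ",".join(sorted(ses.lfp)), ses.n_cells,
             ses.duration)
    return ses


def save_results(tables: dict, out_dir, config: AnalysisConfig | None = None,
                 seed: int | None = None, overwrite: bool = False) -> list:
    """Write one TSV per named DataFrame plus a JSON run manifest.

    Re-running with identical inputs reproduces byte-identical files: floats
    are serialized with repr-faithful formatting and the manifest carries the
    config hash and seed rather than timestamps.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        target = out_dir / f"{name}.tsv"
        if target.exists() and not overwrite:
            raise FileExistsError(f"{target} exists; pass overwrite=True")
        df = df if isinstance(df, pd.DataFrame) else pd.DataFrame(df)
        df.to_csv(target, sep="\t", index=False, float_format="%.10g",
                  lineterminator="\n")
        written.append(target)
    if not tables:
        log.warning("save_results called with no tables; writing manifest only")
    manifest = {
        "tables": sorted(t.name for t in written),
        "config_hash": config.config_hash() if config is not None else None,
        "seed": seed,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    mpath = out_dir / "manifest.json"
    if mpath.exists() and not overwrite:
        raise FileExistsError(f"{mpath} exists; pass overwrite=True")
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written
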
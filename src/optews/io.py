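"""Readers, writers, deterministic test fixtures, and the electronic-circuit
dataset loader.

Interchange format is tidy long-form CSV (one row per seed x coupling x
node) with a comment header carrying the package version and config hash,
so any table can be traced back to the exact configuration that produced
it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__

__all__ = [
    "read_series",
    "write_sweep_table",
    "read_sweep_table",
    "write_run",
    "read_run",
    "CircuitDataset",
    "load_circuit_dataset",
    "normalize_entropy_trace",
    "fixture_generator",
]


def read_series(path, column: int | None = None) -> np.ndarray:
    """Read a delimited-text series file (comma or tab, optional header).

    One column per node, one row per sample.  Returns the full (T, N) array,
    or a single column if ``column`` is given (0-based).
    """
    with open(path) as fh:
        first = "#"
        while first.startswith("#"):
            first = fh.readline()
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    # a file without a header gets numeric-looking column names; detect by
    # trying to coerce the header row
    try:
        header_vals = [float(c) for c in df.columns]
        arr = np.vstack([np.array(header_vals), df.to_numpy(dtype=float)])
    except (TypeError, ValueError):
        arr = df.to_numpy(dtype=float)
    if column is not None:
        return arr[:, column]
    return arr


def _stamp(fh, cfg_hash: str | None):
    fh.write(f"# optews {__version__}\n")
    if cfg_hash:
        fh.write(f"# config_hash {cfg_hash}\n")


def write_sweep_table(
    results, degrees, path, cfg_hash: str | None = None
) -> pd.DataFrame:
    """Write sweep realizations as a tidy table.

    One row per (seed, coupling, node) with columns for degree, H, HT,
    sigma_f, ac1 and the network-level R at that coupling.
    """
    rows = []
    for r in results:
        for j, d in enumerate(r.d_grid):
            for i in range(r.H.shape[1]):
                rows.append({
                    "seed": r.seed, "direction": r.direction, "d": d,
                    "node": i, "degree": int(degrees[i]),
                    "H": r.H[j, i], "HT": r.HT[j, i],
                    "sigma_f": r.sigma_f[j, i], "ac1": r.ac1[j, i],
                    "R": r.R[j],
                })
    df = pd.DataFrame(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        _stamp(fh, cfg_hash)
        df.to_csv(fh, index=False)
    return df


def read_sweep_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_run(run, path) -> Path:
    """Save a simulation run to a columnar binary container (.npz) with its
    configuration echoed in a JSON metadata block."""
    import json

    path = Path(path).with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {"coupling": np.array(run.coupling)}
    if isinstance(run.observables, list):
        for i, o in enumerate(run.observables):
            arrays[f"obs_{i}"] = o
        arrays["n_obs_nodes"] = np.array(len(run.observables))
    else:
        arrays["observables"] = run.observables
    if run.phases is not None:
        arrays["phases"] = run.phases
    meta = {k: v for k, v in run.meta.items() if np.isscalar(v) or v is None}
    arrays["meta_json"] = np.array(
        json.dumps({"family": run.family, "version": __version__, **meta})
    )
    np.savez_compressed(path, **arrays)
    return path


def read_run(path) -> dict:
    """Load a container written by :func:`write_run` as a plain dict."""
    import json

    with np.load(path, allow_pickle=False) as z:
        out = {k: z[k] for k in z.files if k != "meta_json"}
        out["meta"] = json.loads(str(z["meta_json"]))
    return out


@dataclass
class CircuitDataset:
    """Voltage recordings of a star of electronic oscillators, one series
    per node per coupling step."""

    couplings: np.ndarray
    series: list[np.ndarray]  # one (T, N) array per coupling step
    node_labels: list[str]
    hub: int
    sampling_rate_hz: float
    transition: str  # "continuous" | "explosive"

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)


def load_circuit_dataset(path) -> CircuitDataset:
    """Load a locally stored circuit-network recording.

    Expected layout (documented, not auto-downloaded)::

        <path>/
          metadata.yaml   # sampling_rate_hz, transition, node_labels,
                          # hub_label, couplings: [..]
          coupling_000.csv, coupling_001.csv, ...   # one column per node

    Each CSV holds the voltage series of every node at one coupling step,
    columns ordered as ``node_labels``.
    """
    path = Path(path)
    meta_file = path / "metadata.yaml"
    if not meta_file.exists():
        raise FileNotFoundError(
            f"no metadata.yaml under {path}; expected a directory with "
            "metadata.yaml and coupling_NNN.csv files (one voltage column "
            "per node, rows = samples)"
        )
    with open(meta_file) as fh:
        meta = yaml.safe_load(fh)
    required = {"sampling_rate_hz", "transition", "node_labels", "hub_label",
                "couplings"}
    missing = required - set(meta)
    if missing:
        raise ValueError(f"metadata.yaml is missing keys: {sorted(missing)}")
    labels = list(meta["node_labels"])
    if meta["hub_label"] not in labels:
        raise ValueError(f"hub_label {meta['hub_label']!r} not in node_labels")
    couplings = np.asarray(meta["couplings"], dtype=float)
    if len(couplings) < 2:
        raise ValueError("need at least 2 coupling steps")
    series = []
    for j in range(len(couplings)):
        f = path / f"coupling_{j:03d}.csv"
        if not f.exists():
            raise FileNotFoundError(f"missing series file {f}")
        arr = read_series(f)
        if arr.shape[1] != len(labels):
            raise ValueError(
                f"{f}: expected {len(labels)} columns, found {arr.shape[1]}"
            )
        series.append(arr)
    return CircuitDataset(
        couplings=couplings,
        series=series,
        node_labels=labels,
        hub=labels.index(meta["hub_label"]),
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        transition=str(meta["transition"]),
    )


def normalize_entropy_trace(ht_series, baseline_value: float) -> np.ndarray:
    """Entropy trace divided by its uncoupled (zero-coupling) value, so that
    departures from 1 measure relative change."""
    if baseline_value <= 0:
        raise ValueError("baseline entropy must be positive to normalize")
    return np.asarray(ht_series, dtype=float) / baseline_value


def fixture_generator(kind: str, seed: int, outdir) -> Path:
    """Write a small deterministic dataset for tests and demos.

    Kinds: ``white-noise`` (H and HT near 1), ``periodic`` (H, HT known in
    closed form), ``chialvo-orbit`` (isolated neural-map orbit with spikes),
    ``circuit-layout`` (a miniature synthetic directory mimicking the
    circuit-dataset layout; labelled synthetic, not recorded hardware).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if kind == "white-noise":
        x = rng.uniform(size=60000)
        f = outdir / "white_noise.csv"
        np.savetxt(f, x[:, None], delimiter=",", fmt="%.9f")
        return f
    if kind == "periodic":
        x = np.tile([0.0, 1.0, 2.0, 1.5], 600)
        f = outdir / "periodic.csv"
        np.savetxt(f, x[:, None], delimiter=",", fmt="%.3f")
        return f
    if kind == "chialvo-orbit":
        from .dynamics import simulate_chialvo
        from .networks import build_star

        # isolated neuron: a star with zero coupling, keep the hub column
        net = build_star(3)
        run = simulate_chialvo(
            net, np.full(3, 0.05), d=0.0, n_iter=5000, transient=2000,
            seed=seed,
        )
        f = outdir / "chialvo_orbit.csv"
        np.savetxt(f, run.observables[:, [0]], delimiter=",", fmt="%.9f")
        return f
    if kind == "circuit-layout":
        from .dynamics import simulate_rossler
        from .networks import build_star, rossler_frequencies

        net = build_star(6)
        w = rossler_frequencies(net, rng, star_leaf_disorder=1e-3)
        couplings = [0.0, 0.002]
        meta = {
            "sampling_rate_hz": 100.0,
            "transition": "explosive",
            "node_labels": ["hub"] + [f"leaf{i}" for i in range(1, 6)],
            "hub_label": "hub",
            "couplings": couplings,
            "synthetic": True,
        }
        with open(outdir / "metadata.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)
        for j, d in enumerate(couplings):
            run = simulate_rossler(
                net, w, d, t_total=300.0, transient=100.0, seed=seed
            )
            # the sampled y variable plays the role of the recorded voltage
            np.savetxt(
                outdir / f"coupling_{j:03d}.csv", run.meta["y_samples"],
                delimiter=",", fmt="%.6f",
            )
        return outdir
    raise ValueError(f"unknown fixture kind {kind!r}")
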
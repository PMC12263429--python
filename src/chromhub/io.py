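"""Shared I/O helpers: bedGraph, run manifests, checksums.

bedGraph is the canonical coverage dialect (text, diffable); BED writers
live next to their data types in :mod:`chromhub.locus` and
:mod:`chromhub.mcc`, XYZ output in :mod:`chromhub.polymer`.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import sys

import numpy as np

from .locus import GenomicInterval

logger = logging.getLogger("chromhub")


def setup_logging(level=logging.INFO):
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


def write_bedgraph(path, chrom: str, starts, ends, values):
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, values):
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.6g}\n")


def read_bedgraph(path):
    """Read a bedGraph into (chrom, starts, ends, values) arrays.

    Positions are kept 0-based half-open (bedGraph convention)."""
    chroms, starts, ends, values = [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            c, s, e, v = line.split()
            chroms.append(c)
            starts.append(int(s))
            ends.append(int(e))
            values.append(float(v))
    return chroms, np.array(starts), np.array(ends), np.array(values)


def bedgraph_to_dense(path, region: GenomicInterval) -> np.ndarray:
    """Expand a bedGraph to a per-bp array over ``region``."""
    _c, starts, ends, values = read_bedgraph(path)
    cov = np.zeros(len(region))
    for s, e, v in zip(starts, ends, values):
        a = max(0, s - region.start)
        b = min(len(cov), e - region.start)
        if b > a:
            cov[a:b] = v
    return cov


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(seed: int, config: dict, inputs: list | None = None) -> dict:
    from . import __version__

    return {
        "seed": seed,
        "config": config,
        "version": __version__,
        "inputs": {str(p): sha256_of(p) for p in (inputs or [])},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }


def write_manifest(manifest: dict, path):
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
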
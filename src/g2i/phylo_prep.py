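"""Phylogeny-dataset assembly: PID, single-linkage clustering, cluster-count
threshold search, capped stratified sampling and set assembly.

Pairwise percent identity (PID) uses the same global affine aligner as the
boundary module, with the shorter of the two unaligned sequence lengths as
denominator. Single-linkage clusters are the connected components of the
graph with an edge wherever PID >= threshold, so the cluster count is a
non-decreasing step function of the threshold; threshold_for_k exploits
that monotonicity to find a threshold producing exactly k clusters (the
reference analysis chose 17.5% to obtain exactly 30 TerL clusters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .boundary_context import percent_identity

__all__ = [
    "percent_identity", "pid_matrix", "single_linkage", "threshold_for_k",
    "stratified_sample", "assemble_set", "ClusterSet", "SampledSet",
]


@dataclass
class ClusterSet:
    threshold: float
    clusters: list[list[str]]  # partition of the input ids

    @property
    def k(self) -> int:
        return len(self.clusters)


@dataclass
class SampledSet:
    strata: dict[str, list[str]]
    cap: int
    seed: int
    sampled_ids: dict[str, list[str]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.sampled_ids.values())


def pid_matrix(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """All-pairs PID matrix (symmetric, diagonal 100)."""
    ids = list(seqs)
    n = len(ids)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = percent_identity(seqs[ids[i]], seqs[ids[j]])
    return ids, m


def _check_matrix(ids: list[str], m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (len(ids), len(ids)):
        raise ValueError("pid matrix shape does not match ids")
    if not np.allclose(m, m.T):
        raise ValueError("pid matrix must be symmetric")
    return m


def single_linkage(ids: list[str], pid: np.ndarray, threshold: float) -> ClusterSet:
    """Connected components of the >=threshold similarity graph."""
    m = _check_matrix(ids, pid)
    adj = csr_matrix((m >= threshold).astype(np.int8))
    n_comp, labels = connected_components(adj, directed=False)
    clusters: dict[int, list[str]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(ids[i])
    out = sorted((sorted(v) for v in clusters.values()), key=lambda c: c[0])
    return ClusterSet(threshold=threshold, clusters=out)


def cluster_count(ids: list[str], pid: np.ndarray, threshold: float) -> int:
    return single_linkage(ids, pid, threshold).k


def threshold_for_k(ids: list[str], pid: np.ndarray, k: int) -> float | None:
    """A threshold yielding exactly k clusters, or None if infeasible.

    The count is piecewise constant between consecutive distinct
    off-diagonal PID values; each interval is probed once and the midpoint
    of the feasible interval is returned.
    """
    if not 1 <= k <= len(ids):
        raise ValueError("need 1 <= k <= number of sequences")
    m = _check_matrix(ids, pid)
    n = len(ids)
    if n == 1:
        return 50.0 if k == 1 else None
    off = sorted({float(m[i, j]) for i in range(n) for j in range(i + 1, n)})
    # representative thresholds: below all values, between consecutive
    # values, above all values
    probes: list[tuple[float, float, float]] = []  # (probe, lo, hi)
    probes.append((off[0] - 1.0, min(0.0, off[0] - 2.0), off[0]))
    for a, b in zip(off, off[1:]):
        probes.append(((a + b) / 2.0, a, b))
    probes.append((off[-1] + 1.0, off[-1], max(100.0, off[-1] + 2.0)))
    for probe, lo, hi in probes:
        if cluster_count(ids, m, probe) == k:
            return (lo + hi) / 2.0
    return None


def stratified_sample(
    strata: dict[str, list[str]], cap: int, seed: int
) -> SampledSet:
    """Uniform without-replacement sampling of at most cap ids per stratum,
    deterministic under seed."""
    if cap < 0:
        raise ValueError("cap must be >= 0")
    rng = np.random.default_rng(seed)
    sampled: dict[str, list[str]] = {}
    for label in sorted(strata):
        members = sorted(strata[label])
        take = min(cap, len(members))
        idx = sorted(rng.choice(len(members), size=take, replace=False))
        sampled[label] = [members[i] for i in idx]
    return SampledSet(strata=strata, cap=cap, seed=seed, sampled_ids=sampled)


def assemble_set(
    groups: list[tuple[str, dict[str, str]]], out_fasta: str | Path | None = None
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Concatenate labelled sequence groups into one set.

    Ids are prefixed "label|id" for provenance; a duplicate id after
    prefixing is an error. Returns (records, manifest) where the manifest
    carries per-group counts and the total.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    rows = []
    for label, seqs in groups:
        for sid, seq in seqs.items():
            full = f"{label}|{sid}"
            if full in seen:
                raise ValueError(f"duplicate sequence id {full!r}")
            seen.add(full)
            records.append((full, seq))
        rows.append({"group": label, "n": len(seqs)})
    manifest = pd.DataFrame(rows, columns=["group", "n"])
    manifest.loc[len(manifest)] = {"group": "total", "n": int(manifest["n"].sum())}
    if out_fasta is not None:
        from .core_io import write_fasta

        write_fasta(records, out_fasta)
    return records, manifest
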
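"""Persistence diagrams and partition selection.

The persistence probabilities' diagram plots, for every partition in a
nested sequence indexed by its cluster count q, the q per-cluster
persistence probabilities.  Two selection rules operate on it:

* *finest alpha-partition* (unsupervised): among the scanned partitions
  whose minimum persistence is at least alpha, take the one with the
  largest q.  The trivial partition (q = 1, persistence 1) always
  qualifies, so a result always exists.
* *largest drop* (supervised heuristic): take the q maximizing the fall
  of the minimum persistence from q to q+1 — a sudden drop marks the
  step at which a genuine community is first broken.  The trivial
  q = 1 -> 2 step is excluded, since persistence 1 at q = 1 holds by
  construction and would otherwise dominate.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np

from .errors import ParseError, ValidationError
from .graph import Network
from .markov import TransitionModel
from .partitions import partition_sequence, select_horizon, HorizonScan
from .quality import Partition, lump

__all__ = [
    "PersistenceDiagram",
    "DetectionResult",
    "persistence_diagram",
    "find_finest_alpha_partition",
    "detect_drop",
    "export_diagram",
    "load_diagram",
    "detect_communities",
]


@dataclasses.dataclass(frozen=True)
class DiagramEntry:
    q: int
    persistence: np.ndarray
    partition: Partition | None  # None for diagrams re-loaded from disk


@dataclasses.dataclass
class PersistenceDiagram:
    entries: list[DiagramEntry]
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.entries:
            if len(e.persistence) != e.q:
                raise ValidationError(
                    f"diagram entry for q={e.q} has {len(e.persistence)} values"
                )
        qs = [e.q for e in self.entries]
        if len(set(qs)) != len(qs):
            raise ValidationError("duplicate q in persistence diagram")

    @property
    def qs(self) -> list[int]:
        return [e.q for e in self.entries]

    def entry(self, q: int) -> DiagramEntry:
        for e in self.entries:
            if e.q == q:
                return e
        raise ValidationError(f"no diagram entry for q={q}")

    def min_persistence(self, q: int) -> float:
        return float(self.entry(q).persistence.min())

    def min_curve(self) -> dict[int, float]:
        return {e.q: float(e.persistence.min()) for e in self.entries}


@dataclasses.dataclass
class DetectionResult:
    q: int
    partition: Partition | None
    mode: str  # "alpha" or "drop"
    alpha: float | None
    persistence: np.ndarray
    min_curve: dict[int, float]

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "alpha": self.alpha,
            "selected_q": self.q,
            "persistence": [float(x) for x in self.persistence],
            "min_persistence_curve": {
                str(k): v for k, v in sorted(self.min_curve.items())
            },
        }


def persistence_diagram(
    model: TransitionModel,
    partitions: list[Partition],
    provenance: dict | None = None,
) -> PersistenceDiagram:
    """Lump the chain over every partition and collect diag(U) per q."""
    entries = []
    for part in partitions:
        chain = lump(model, part)
        entries.append(
            DiagramEntry(q=part.q, persistence=chain.persistence, partition=part)
        )
    entries.sort(key=lambda e: e.q)
    return PersistenceDiagram(entries=entries, provenance=dict(provenance or {}))


def find_finest_alpha_partition(
    diag: PersistenceDiagram, alpha: float
) -> DetectionResult:
    """Largest-q scanned partition whose every cluster is an alpha-community."""
    if not (0 < alpha <= 1):
        raise ValidationError("alpha must lie in (0, 1]")
    if not diag.entries:
        raise ValidationError("empty persistence diagram")
    best = None
    for e in diag.entries:
        if float(e.persistence.min()) >= alpha:
            if best is None or e.q > best.q:
                best = e
    if best is None:
        # the scanned sequence did not include q=1; report the best available
        raise ValidationError(
            "no scanned partition meets alpha; include the trivial partition "
            "(q=1) in the sequence to guarantee a result"
        )
    return DetectionResult(
        q=best.q,
        partition=best.partition,
        mode="alpha",
        alpha=alpha,
        persistence=best.persistence,
        min_curve=diag.min_curve(),
    )


def detect_drop(diag: PersistenceDiagram) -> DetectionResult:
    """q maximizing the drop of the minimum persistence from q to q+1.

    Scans q >= 2 (the trivial step is excluded); ties break toward the
    smallest q.  Requires the diagram to contain some consecutive pair
    (q, q+1) with q >= 2.
    """
    curve = diag.min_curve()
    drops: list[tuple[int, float]] = []
    for q in sorted(curve):
        if q >= 2 and (q + 1) in curve:
            drops.append((q, curve[q] - curve[q + 1]))
    if not drops:
        raise ValidationError(
            "diagram must cover consecutive q and q+1 for some q >= 2"
        )
    best_q, best_drop = max(drops, key=lambda t: (t[1], -t[0]))
    if all(abs(d) < 1e-15 for _, d in drops):
        warnings.warn(
            "min-persistence curve is flat: no community structure detected; "
            "returning the smallest eligible q",
            stacklevel=2,
        )
    e = diag.entry(best_q)
    return DetectionResult(
        q=best_q,
        partition=e.partition,
        mode="drop",
        alpha=None,
        persistence=e.persistence,
        min_curve=curve,
    )


def export_diagram(diag: PersistenceDiagram, path, format: str = "tsv") -> None:
    """Write the diagram as TSV rows (q, cluster_index, persistence) or JSON."""
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("q\tcluster\tpersistence\n")
            for e in diag.entries:
                for c, p in enumerate(e.persistence):
                    fh.write(f"{e.q}\t{c}\t{p:.15g}\n")
    elif format == "json":
        payload = {
            "provenance": diag.provenance,
            "diagram": {
                str(e.q): [float(p) for p in e.persistence] for e in diag.entries
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    else:
        raise ValidationError("format must be 'tsv' or 'json'")


def load_diagram(path, format: str = "tsv") -> PersistenceDiagram:
    """Re-import an exported diagram (persistence values only)."""
    if format == "tsv":
        per_q: dict[int, dict[int, float]] = {}
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("q\t"):
                raise ParseError(f"{path}: missing diagram header")
            for lineno, line in enumerate(fh, start=2):
                line = line.strip()
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ParseError(f"{path}: line {lineno}: expected 3 columns")
                q, c, p = int(parts[0]), int(parts[1]), float(parts[2])
                per_q.setdefault(q, {})[c] = p
        entries = []
        for q in sorted(per_q):
            vec = np.array([per_q[q][c] for c in range(q)])
            entries.append(DiagramEntry(q=q, persistence=vec, partition=None))
        return PersistenceDiagram(entries=entries)
    if format == "json":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        entries = [
            DiagramEntry(q=int(q), persistence=np.array(v), partition=None)
            for q, v in payload["diagram"].items()
        ]
        entries.sort(key=lambda e: e.q)
        return PersistenceDiagram(entries=entries,
                                  provenance=payload.get("provenance", {}))
    raise ValidationError("format must be 'tsv' or 'json'")


def detect_communities(
    net: Network,
    alpha: float | None = None,
    drop: bool = False,
    T_max: int | None = None,
    linkage: str = "average",
    q_max: int | None = None,
) -> tuple[DetectionResult, PersistenceDiagram, HorizonScan]:
    """Full pipeline: horizon scan, dendrogram, diagram, selection.

    Exactly one of ``alpha`` (finest alpha-partition) or ``drop``
    (largest-drop heuristic) chooses the selection rule.  ``q_max``
    defaults to min(N, 30).
    """
    if (alpha is None) == (not drop):
        raise ValidationError("choose exactly one of alpha=... or drop=True")
    model = TransitionModel.from_network(net)
    scan = select_horizon(model, T_max=T_max, linkage=linkage)
    dend = scan.selected_dendrogram
    if q_max is None:
        q_max = min(net.N, 30)
    parts = partition_sequence(dend, q_max)
    diag = persistence_diagram(
        model,
        parts,
        provenance={
            "horizon_T": scan.selected_T,
            "linkage": linkage,
            "q_max": q_max,
            "alpha": alpha,
        },
    )
    if drop:
        result = detect_drop(diag)
    else:
        result = find_finest_alpha_partition(diag, alpha)
    return result, diag, scan
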
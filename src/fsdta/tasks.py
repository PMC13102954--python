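"""Protein-anchored task construction and meta-splits.

Every task bundles all affinity records sharing one target protein, with a
support/query partition for episodic training.  Tasks are split into
meta-train / meta-validation / meta-test either at random (largest-remainder
8:1:1 by default) or by sequence-identity clustering ("novel" split), which
guarantees that no protein in one partition has >= threshold global-alignment
identity with a protein in another partition — the cold-target setting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .featurization import AffinityRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ScreeningRecord",
    "SplitStrategy",
    "Task",
    "TaskSplit",
    "build_screening_tasks",
    "build_tasks",
    "cluster_by_identity",
    "largest_remainder",
    "pairwise_identity",
    "read_clstr",
    "sample_support_query",
    "split_novel",
    "split_random",
    "write_split_manifest",
]


class SplitStrategy(str, Enum):
    RANDOM = "random"
    NOVEL = "novel"


@dataclass(frozen=True)
class Task:
    """One target protein with its records and a support/query partition."""

    target_id: str
    records: tuple
    support_idx: tuple[int, ...] = ()
    query_idx: tuple[int, ...] = ()

    def __post_init__(self):
        s, q = set(self.support_idx), set(self.query_idx)
        if s & q:
            raise ValueError(f"task {self.target_id}: support/query overlap")
        n = len(self.records)
        if any(not 0 <= i < n for i in s | q):
            raise ValueError(f"task {self.target_id}: partition index out of range")

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def support(self) -> list:
        return [self.records[i] for i in self.support_idx]

    @property
    def query(self) -> list:
        return [self.records[i] for i in self.query_idx]


@dataclass(frozen=True)
class TaskSplit:
    train: tuple[Task, ...]
    validation: tuple[Task, ...]
    test: tuple[Task, ...]
    strategy: SplitStrategy
    seed: int

    def __post_init__(self):
        ids = [t.target_id for part in (self.train, self.validation, self.test) for t in part]
        if len(ids) != len(set(ids)):
            raise ValueError("partitions are not disjoint by target_id")

    @property
    def all_tasks(self) -> tuple[Task, ...]:
        return self.train + self.validation + self.test


def build_tasks(records: Sequence[AffinityRecord], min_records: int = 2) -> list[Task]:
    """Group records by target protein; drop tasks below ``min_records``.

    The default ``min_records=2`` leaves room for a non-empty query set next
    to a 1-record support; callers training with support size ``n`` should
    pass ``min_records = n + 1``.
    """
    by_target: dict[str, list[AffinityRecord]] = {}
    for r in records:
        by_target.setdefault(r.protein.target_id, []).append(r)
    tasks, dropped = [], 0
    for tid in sorted(by_target):
        recs = by_target[tid]
        if len(recs) < min_records:
            dropped += 1
            continue
        tasks.append(Task(target_id=tid, records=tuple(recs)))
    if dropped:
        logger.info("dropped %d tasks with fewer than %d records", dropped, min_records)
    return tasks


def largest_remainder(n: int, ratio: Sequence[float]) -> list[int]:
    """Apportion ``n`` items to parts proportional to ``ratio`` exactly."""
    ratio = np.asarray(ratio, dtype=np.float64)
    if np.any(ratio <= 0):
        raise ValueError("ratio components must be positive")
    quota = n * ratio / ratio.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    # hand out leftover seats to the largest remainders (stable order on ties)
    for i in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def split_random(tasks: Sequence[Task], ratio: Sequence[float] = (8, 1, 1), seed: int = 0) -> TaskSplit:
    """Shuffle tasks and allocate counts by largest-remainder rounding."""
    if len(tasks) < 3:
        raise ValueError("need at least one task per partition")
    counts = largest_remainder(len(tasks), ratio)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tasks))
    shuffled = [tasks[i] for i in order]
    a, b = counts[0], counts[0] + counts[1]
    return TaskSplit(
        train=tuple(shuffled[:a]),
        validation=tuple(shuffled[a:b]),
        test=tuple(shuffled[b:]),
        strategy=SplitStrategy.RANDOM,
        seed=seed,
    )


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches / alignment length (incl. gaps)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def cluster_by_identity(sequences: Mapping[str, str], threshold: float = 0.4) -> list[list[str]]:
    """Greedy incremental clustering at a global-identity threshold.

    Sequences are sorted by length descending; each joins the first cluster
    whose *representative* (founding, longest member) has identity >=
    threshold, else founds a new cluster.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    clusters: list[list[str]] = []
    for sid in order:
        for cluster in clusters:
            if pairwise_identity(sequences[cluster[0]], sequences[sid]) >= threshold:
                cluster.append(sid)
                break
        else:
            clusters.append([sid])
    return clusters


def read_clstr(path) -> list[list[str]]:
    """Parse a CD-HIT ``.clstr`` file into id clusters (parity-run hook)."""
    clusters: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">Cluster"):
                clusters.append([])
            elif line:
                # e.g. "0	123aa, >P12345... *"
                sid = line.split(">", 1)[1].split("...")[0]
                clusters[-1].append(sid)
    return [c for c in clusters if c]


def split_novel(
    tasks: Sequence[Task],
    sequences: Mapping[str, str],
    threshold: float = 0.4,
    ratio: Sequence[float] = (8, 1, 1),
    seed: int = 0,
    clusters: list[list[str]] | None = None,
) -> TaskSplit:
    """Cluster proteins by identity, then allocate whole clusters to partitions.

    Target task counts follow largest-remainder apportionment of ``ratio``;
    clusters are shuffled with ``seed`` then greedily assigned, largest first,
    to the partition with the largest remaining deficit (train wins ties), so
    no protein pair >= threshold identity ever crosses a partition boundary.
    """
    if clusters is None:
        clusters = cluster_by_identity({t.target_id: sequences[t.target_id] for t in tasks}, threshold)
    if len(clusters) < 3:
        raise ValueError("need at least 3 identity clusters to form 3 partitions")
    by_id = {t.target_id: t for t in tasks}
    targets = largest_remainder(len(tasks), ratio)
    rng = np.random.default_rng(seed)
    shuffled = [clusters[i] for i in rng.permutation(len(clusters))]
    shuffled.sort(key=len, reverse=True)  # stable: keeps the shuffle within equal sizes
    assigned: list[list[list[str]]] = [[], [], []]  # clusters per partition
    filled = [0, 0, 0]
    for cluster in shuffled:
        deficits = [targets[p] - filled[p] for p in range(3)]
        p = int(np.argmax(deficits))
        assigned[p].append(cluster)
        filled[p] += len(cluster)
    # repair pass: a partition with a positive target must not end up empty;
    # move the smallest whole cluster out of the partition holding the most
    for p in range(3):
        if targets[p] > 0 and not assigned[p]:
            donor = max(range(3), key=lambda q: len(assigned[q]))
            if len(assigned[donor]) <= 1:
                raise ValueError("too few identity clusters to fill all partitions")
            assigned[donor].sort(key=len, reverse=True)
            assigned[p].append(assigned[donor].pop())
    parts = [
        [by_id[sid] for cluster in assigned[p] for sid in cluster if sid in by_id]
        for p in range(3)
    ]
    return TaskSplit(
        train=tuple(parts[0]),
        validation=tuple(parts[1]),
        test=tuple(parts[2]),
        strategy=SplitStrategy.NOVEL,
        seed=seed,
    )


def sample_support_query(task: Task, support_size: int, seed_or_rng) -> Task:
    """Uniform draw (without replacement) of a support set; rest is the query."""
    if support_size >= task.n_records:
        raise ValueError(
            f"task {task.target_id}: support_size {support_size} >= {task.n_records} records"
        )
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    support = rng.choice(task.n_records, size=support_size, replace=False)
    support_set = set(int(i) for i in support)
    query = tuple(i for i in range(task.n_records) if i not in support_set)
    return replace(task, support_idx=tuple(sorted(support_set)), query_idx=query)


@dataclass(frozen=True)
class ScreeningRecord:
    """An affinity record carrying an active/inactive screening flag."""

    record: AffinityRecord
    active: bool


def build_screening_tasks(
    activity_records: Sequence[ScreeningRecord],
    support_actives: int = 15,
    seed: int = 0,
    test_targets: Sequence[str] = (),
) -> tuple[list[Task], list[Task]]:
    """Episodic screening tasks with active-only support sets.

    Training tasks keep actives only (support = ``support_actives`` sampled
    actives, query = remaining actives).  Test tasks (``test_targets``) keep
    everything: support = sampled actives, query = all remaining actives plus
    every inactive, flags retained for ranking evaluation.  Tasks with too few
    actives are dropped with a log line.

    Returned task records are ``ScreeningRecord``s; use ``r.record`` for the
    featurized pair and ``r.active`` for the flag.
    """
    rng = np.random.default_rng(seed)
    by_target: dict[str, list[ScreeningRecord]] = {}
    for sr in activity_records:
        by_target.setdefault(sr.record.protein.target_id, []).append(sr)
    train_tasks, test_tasks = [], []
    test_set = set(test_targets)
    for tid in sorted(by_target):
        recs = by_target[tid]
        active_idx = [i for i, sr in enumerate(recs) if sr.active]
        if len(active_idx) <= support_actives:
            logger.info("dropping screening task %s: only %d actives", tid, len(active_idx))
            continue
        chosen = set(int(i) for i in rng.choice(active_idx, size=support_actives, replace=False))
        if tid in test_set:
            query = tuple(i for i in range(len(recs)) if i not in chosen)
            test_tasks.append(Task(tid, tuple(recs), tuple(sorted(chosen)), query))
        else:
            actives = [recs[i] for i in active_idx]
            remap = {old: new for new, old in enumerate(active_idx)}
            chosen_new = tuple(sorted(remap[i] for i in chosen))
            query = tuple(i for i in range(len(actives)) if i not in set(chosen_new))
            train_tasks.append(Task(tid, tuple(actives), chosen_new, query))
    return train_tasks, test_tasks


def write_split_manifest(split: TaskSplit, path) -> None:
    """TSV manifest: target_id <tab> partition."""
    with open(path, "w") as fh:
        fh.write("target_id\tpartition\n")
        for name, part in (("train", split.train), ("validation", split.validation), ("test", split.test)):
            for t in part:
                fh.write(f"{t.target_id}\t{name}\n")
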
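"""Resource-aware worker selection and cyclic data partitioning.

The worker count for a task is capped by four bounds at once:

    k = min(C, C_u, floor(M / m), l)

with C the machine's cores, C_u the user's core cap, M main memory in
GB, m the per-process memory need in GB, and l the number of data
elements. Elements are then dealt cyclically: element j (1-based) goes
to worker ((j - 1) mod k) + 1, i.e. worker p receives elements
p, p + k, p + 2k, ... — with 24 chromosomes and k = 7, worker 1 gets
{1, 8, 15, 22} and worker 7 gets {7, 14, 21}.

``parallel_map`` runs a pure function over the chunks (serially for
k = 1, via ``multiprocessing`` otherwise) and restores the original
element order on merge, so results are identical for any worker count.
"""

from __future__ import annotations

import math
import multiprocessing
import os
import warnings
from dataclasses import dataclass
from typing import Any, Callable, Sequence, TypeVar

from .errors import ResourceError, SekitError, UsageError

T = TypeVar("T")

# default per-process memory needs in GB, by task
TASK_MEMORY_GB = {"stitch": 3.0, "profile": 2.0, "gsea": 2.0, "motif": 2.0}


@dataclass(frozen=True)
class ResourceSpec:
    """Machine resources and user caps driving worker-count selection."""

    cores: int  # C: available cores
    user_cores: int  # C_u: user cap
    memory_gb: float  # M: main memory
    task_memory_gb: float = TASK_MEMORY_GB["stitch"]  # m_i

    def __post_init__(self) -> None:
        if self.cores < 1 or self.user_cores < 1:
            raise UsageError("core counts must be >= 1")
        if self.memory_gb <= 0 or self.task_memory_gb <= 0:
            raise UsageError("memory values must be positive")

    @classmethod
    def detect(cls, user_cores: int | None = None, memory_gb: float | None = None,
               task_memory_gb: float = TASK_MEMORY_GB["stitch"]) -> "ResourceSpec":
        """Best-effort autodetection, overridable per field."""
        cores = os.cpu_count() or 1
        if memory_gb is None:
            try:
                memory_gb = (
                    os.sysconf("SC_PAGE_SIZE") * os.sysconf("SC_PHYS_PAGES") / 1024**3
                )
            except (ValueError, OSError):
                memory_gb = 4.0
        return cls(
            cores=cores,
            user_cores=user_cores if user_cores is not None else cores,
            memory_gb=memory_gb,
            task_memory_gb=task_memory_gb,
        )


def n_processes(spec: ResourceSpec, n_elements: int) -> int:
    """Worker count: min of cores, user cap, memory quota and data size."""
    if n_elements < 1:
        raise UsageError("need at least one data element")
    mem_bound = math.floor(spec.memory_gb / spec.task_memory_gb)
    if mem_bound < 1:
        raise ResourceError(
            f"cannot run one process: {spec.task_memory_gb} GB needed, "
            f"{spec.memory_gb} GB available"
        )
    return min(spec.cores, spec.user_cores, mem_bound, n_elements)


def cyclic_partition(elements: Sequence[T], k: int) -> list[list[T]]:
    """Deal elements cyclically into k chunks.

    Chunk p (1-based) collects every k-th element starting at position
    p. When k exceeds the element count the trailing chunks are empty
    (with a warning); callers going through :func:`n_processes` never
    see that case, since k is capped at the element count.
    """
    if k < 1:
        raise UsageError(f"k must be >= 1, got {k}")
    if k > len(elements):
        warnings.warn(f"{k} chunks requested for {len(elements)} elements; "
                      f"{k - len(elements)} chunks will be empty")
    chunks: list[list[T]] = [[] for _ in range(k)]
    for j, element in enumerate(elements):
        chunks[j % k].append(element)
    return chunks


def _run_chunk(args: tuple[int, Callable[[list], Any], list]) -> tuple[int, Any]:
    idx, task, chunk = args
    return idx, task(chunk)


def parallel_map(task: Callable[[list[T]], list[Any]], chunks: list[list[T]]) -> list[Any]:
    """Apply ``task`` to each chunk and merge results in element order.

    ``task`` must be a pure function of its chunk returning one result
    per element. With a single chunk (or all-but-one empty) execution is
    serial and bit-identical to the parallel path. A failing chunk
    aborts the whole task with the chunk number in the error.
    """
    nonempty = [(i, c) for i, c in enumerate(chunks) if c]
    if len(nonempty) <= 1:
        results = []
        for i, chunk in nonempty:
            try:
                results.append((i, task(chunk)))
            except Exception as exc:
                raise SekitError(f"task failed on chunk {i + 1}: {exc}") from exc
    else:
        with multiprocessing.Pool(processes=len(nonempty)) as pool:
            jobs = [
                (i, pool.apply_async(_run_chunk, [(i, task, chunk)])) for i, chunk in nonempty
            ]
            results = []
            for i, job in jobs:
                try:
                    results.append(job.get())
                except Exception as exc:
                    raise SekitError(f"task failed on chunk {i + 1}: {exc}") from exc
    # interleave chunk results back into original element order
    k = len(chunks)
    per_chunk = {i: list(res) for i, res in results}
    merged: list[Any] = []
    pos = [0] * k
    total = sum(len(c) for c in chunks)
    for j in range(total):
        p = j % k
        merged.append(per_chunk[p][pos[p]])
        pos[p] += 1
    return merged
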
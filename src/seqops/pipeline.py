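"""Composable lazy pipelines, parallel batching, and the prefetch scheduler.

A :class:`Pipeline` is an ordered list of stages:

* ``Mapper(fn)`` — one input, one output;
* ``Flattener(fn)`` — one input, a finite lazy stream of outputs;
* ``PARALLEL`` — a marker: stages after it may run concurrently;
* ``PrefetchStage(fn)`` — a suspendable query task (see below).

``run`` gives the serial semantics every other mode is measured against:
depth-first expansion order, pulling only as much of the source as the
consumer demands.  ``run_parallel`` blocks elements into batches (default
100,000) and processes batches in a thread pool; it promises only multiset
equality with the serial output, except that ``workers=1`` reproduces the
serial sequence exactly.

``run_prefetch`` realizes the batched-lookup transformation for index
queries whose latency is dominated by cache misses.  A prefetch stage is a
generator function that, per element, issues an advisory prefetch hint for
the index location it is about to touch, suspends exactly once, and on
resumption performs the actual access and returns its result.  The
scheduler keeps a ring of M suspended tasks (M = 16 by default): it first
fills the slots from the source, then cyclically resumes them; each
completed task emits its result downstream and hands its slot to a fresh
source element, and after source exhaustion the remaining tasks are
drained.  With M = 1 the loop degenerates to serial execution.  Prefetch
hints are semantically inert here; instrumentation counters and event
traces let tests observe that hints from several tasks really are issued
before any of their loads completes.
"""

from __future__ import annotations

import itertools
from concurrent.futures import FIRST_COMPLETED, ThreadPoolExecutor, wait
from dataclasses import dataclass
from typing import Any, Callable, Generator, Iterable, Iterator

__all__ = [
    "ARG",
    "DEFAULT_M",
    "DEFAULT_BATCH_SIZE",
    "Mapper",
    "Flattener",
    "ParallelMarker",
    "PARALLEL",
    "PrefetchStage",
    "Pipeline",
    "PipelineStageError",
    "PrefetchProtocolError",
    "partial",
    "run",
    "run_parallel",
    "run_prefetch",
]

#: Default number of concurrent suspended query tasks.
DEFAULT_M = 16
#: Default number of elements handed to each parallel worker task.
DEFAULT_BATCH_SIZE = 100_000

_SENTINEL = object()


class PipelineStageError(RuntimeError):
    """Wraps an exception raised inside a stage, identifying the stage."""

    def __init__(self, stage_name: str, original: BaseException):
        super().__init__(f"pipeline stage {stage_name!r} failed: {original!r}")
        self.stage_name = stage_name
        self.original = original


class PrefetchProtocolError(RuntimeError):
    """A prefetch stage suspended more than once, or never."""


@dataclass(frozen=True)
class Mapper:
    fn: Callable[[Any], Any]


@dataclass(frozen=True)
class Flattener:
    fn: Callable[[Any], Iterable[Any]]


class ParallelMarker:
    """Position after which elements may be processed concurrently."""

    def __repr__(self) -> str:  # pragma: no cover
        return "PARALLEL"


PARALLEL = ParallelMarker()


@dataclass(frozen=True)
class PrefetchStage:
    """A suspendable computation with exactly one suspend point.

    ``fn(item)`` must be a generator that yields exactly once — after
    issuing its prefetch hint, before its index access — and then returns
    the stage's result.
    """

    fn: Callable[[Any], Generator[None, None, Any]]


@dataclass(frozen=True)
class Pipeline:
    stages: tuple[Any, ...] = ()

    def __or__(self, stage: Any) -> "Pipeline":
        return Pipeline(self.stages + (stage,))


# ---------------------------------------------------------------------------
# Partial application with an explicit placeholder


class _Placeholder:
    def __repr__(self) -> str:  # pragma: no cover
        return "ARG"


#: The unbound-argument placeholder for :func:`partial`.
ARG = _Placeholder()


def partial(fn: Callable[..., Any], *args: Any, **kwargs: Any) -> Callable[[Any], Any]:
    """Bind all but exactly one positional argument of ``fn``.

    The returned single-argument function substitutes its argument for the
    :data:`ARG` placeholder.  Raises ``TypeError`` unless exactly one
    placeholder is present.
    """
    holes = [i for i, a in enumerate(args) if a is ARG]
    if any(v is ARG for v in kwargs.values()):
        raise TypeError("placeholder is only supported in positional arguments")
    if len(holes) != 1:
        raise TypeError(f"partial requires exactly one unbound slot, found {len(holes)}")
    hole = holes[0]

    def bound(x: Any) -> Any:
        filled = args[:hole] + (x,) + args[hole + 1 :]
        return fn(*filled, **kwargs)

    bound.__name__ = f"partial_{getattr(fn, '__name__', 'fn')}"
    return bound


# ---------------------------------------------------------------------------
# Serial execution


def _stage_name(stage: Any) -> str:
    fn = getattr(stage, "fn", None)
    return getattr(fn, "__name__", None) or type(stage).__name__


def _drive_to_completion(stage: PrefetchStage, item: Any) -> Any:
    """Run a prefetch task serially: start, resume once, take its result."""
    task = _start_task(stage, item)
    done, value = _resume_task(stage, task)
    if not done:
        raise PrefetchProtocolError(
            f"prefetch stage {_stage_name(stage)!r} suspended more than once"
        )
    return value


def _apply_stages(stages: tuple[Any, ...], source: Iterable[Any]) -> Iterator[Any]:
    stream: Iterator[Any] = iter(source)
    for stage in stages:
        if isinstance(stage, ParallelMarker):
            continue  # serial semantics ignore the marker
        stream = _apply_one(stage, stream)
    return stream


def _apply_one(stage: Any, stream: Iterator[Any]) -> Iterator[Any]:
    name = _stage_name(stage)
    if isinstance(stage, Mapper):
        def mapped(it: Iterator[Any]) -> Iterator[Any]:
            for x in it:
                try:
                    y = stage.fn(x)
                except Exception as exc:
                    raise PipelineStageError(name, exc) from exc
                yield y
        return mapped(stream)
    if isinstance(stage, Flattener):
        def flattened(it: Iterator[Any]) -> Iterator[Any]:
            for x in it:
                try:
                    sub = iter(stage.fn(x))
                    while True:
                        try:
                            y = next(sub)
                        except StopIteration:
                            break
                        yield y
                except PipelineStageError:
                    raise
                except Exception as exc:
                    raise PipelineStageError(name, exc) from exc
        return flattened(stream)
    if isinstance(stage, PrefetchStage):
        def prefetched(it: Iterator[Any]) -> Iterator[Any]:
            for x in it:
                try:
                    yield _drive_to_completion(stage, x)
                except PrefetchProtocolError:
                    raise
                except Exception as exc:
                    raise PipelineStageError(name, exc) from exc
        return prefetched(stream)
    raise TypeError(f"unknown pipeline stage {stage!r}")


def run(p: Pipeline | Iterable[Any], source: Iterable[Any]) -> Iterator[Any]:
    """Serial, lazy execution: the reference semantics for every other mode."""
    stages = p.stages if isinstance(p, Pipeline) else tuple(p)
    return _apply_stages(stages, source)


# ---------------------------------------------------------------------------
# Parallel execution over element batches


def _split_at_marker(stages: tuple[Any, ...]) -> tuple[tuple[Any, ...], tuple[Any, ...]]:
    for i, stage in enumerate(stages):
        if isinstance(stage, ParallelMarker):
            return stages[:i], stages[i + 1 :]
    return stages, ()


def _batches(stream: Iterator[Any], size: int) -> Iterator[list[Any]]:
    while True:
        batch = list(itertools.islice(stream, size))
        if not batch:
            return
        yield batch


def run_parallel(
    p: Pipeline | Iterable[Any],
    source: Iterable[Any],
    workers: int = 1,
    batch_size: int = DEFAULT_BATCH_SIZE,
) -> Iterator[Any]:
    """Execute stages after the ``PARALLEL`` marker concurrently over batches.

    Output order is unspecified for ``workers > 1`` (equality with the
    serial run holds as a multiset); ``workers = 1`` reproduces the serial
    sequence exactly.  Stages after the marker must be pure with respect to
    shared state.  The first worker exception is re-raised after all running
    batches drain.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    stages = p.stages if isinstance(p, Pipeline) else tuple(p)
    pre, post = _split_at_marker(stages)
    elements = _apply_stages(pre, source)

    if workers == 1:
        yield from _apply_stages(post, elements)
        return

    def process(batch: list[Any]) -> list[Any]:
        return list(_apply_stages(post, batch))

    batches = _batches(elements, batch_size)
    first_error: BaseException | None = None
    with ThreadPoolExecutor(max_workers=workers) as pool:
        pending = set()
        for batch in itertools.islice(batches, workers + 1):
            pending.add(pool.submit(process, batch))
        while pending:
            done, pending = wait(pending, return_when=FIRST_COMPLETED)
            for fut in done:
                exc = fut.exception()
                if exc is not None:
                    first_error = first_error or exc
                    continue
                if first_error is None:
                    yield from fut.result()
            if first_error is None:
                for batch in itertools.islice(batches, len(done)):
                    pending.add(pool.submit(process, batch))
    if first_error is not None:
        raise first_error


# ---------------------------------------------------------------------------
# Prefetch scheduling


def _start_task(stage: PrefetchStage, item: Any) -> Generator[None, None, Any]:
    """Create a task and advance it to its suspend point (hint issued)."""
    task = stage.fn(item)
    if not hasattr(task, "send"):
        raise PrefetchProtocolError(
            f"prefetch stage {_stage_name(stage)!r} must be a generator function"
        )
    try:
        next(task)
    except StopIteration:
        raise PrefetchProtocolError(
            f"prefetch stage {_stage_name(stage)!r} never suspended"
        ) from None
    return task


def _resume_task(stage: PrefetchStage, task: Generator[None, None, Any]) -> tuple[bool, Any]:
    """Resume a suspended task; (True, result) when it completes."""
    try:
        next(task)
    except StopIteration as stop:
        return True, stop.value
    return False, None


def run_prefetch(
    stage: PrefetchStage | Callable[[Any], Generator[None, None, Any]],
    source: Iterable[Any],
    M: int = DEFAULT_M,
) -> Iterator[Any]:
    """Interleave up to ``M`` suspended query tasks over the source.

    Slots are first populated from the source (each new task runs up to its
    prefetch hint and suspends); the scheduler then cycles over the ring,
    resuming one task per visit.  A completed task's result is emitted and
    its slot is refilled from the source; once the source is exhausted the
    remaining tasks are drained.  Result multiset equals the serial run's;
    ``M = 1`` reproduces serial order exactly.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if not isinstance(stage, PrefetchStage):
        stage = PrefetchStage(stage)
    it = iter(source)
    slots: list[Generator[None, None, Any] | None] = [None] * M
    filled = 0

    # initially populate the slot array
    for i in range(M):
        item = next(it, _SENTINEL)
        if item is _SENTINEL:
            break
        slots[i] = _start_task(stage, item)
        filled += 1

    cursor = 0
    while filled > 0:
        task = slots[cursor]
        if task is not None:
            done, value = _resume_task(stage, task)
            if not done:
                raise PrefetchProtocolError(
                    f"prefetch stage {_stage_name(stage)!r} suspended more than once"
                )
            yield value
            item = next(it, _SENTINEL)
            if item is _SENTINEL:
                slots[cursor] = None
                filled -= 1
            else:
                slots[cursor] = _start_task(stage, item)
        cursor = (cursor + 1) % M
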
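"""PSMC text-output parsing and conversion to calendar-scaled trajectories.

The PSMC program writes one block per EM iteration; each block carries an
``RD`` round number, a ``TR`` line with the scaled mutation and recombination
parameters of that round, one ``RS`` line per atomic time interval
``(k, t_k, lambda_k, ...)`` and a ``PA`` line repeating the ``-p`` pattern,
terminated by ``//``.  Several runs (different ``-p`` settings) may be
concatenated in one stream; a new run is recognised when the round counter
resets.  Only the final iteration block of each run is used.

Times in a run are in units of 2*N0 generations and sizes are multipliers of
N0; ``scale_to_real_units`` converts them to years before present and diploid
individuals with N0 = theta0 / (4 * mu * bin_size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectories import NeTrajectory

__all__ = [
    "PSMCRun",
    "PSMCParseError",
    "parse_psmc_output",
    "read_psmc",
    "write_psmc",
    "select_run",
    "scale_to_real_units",
    "trajectory_to_run",
    "DEFAULT_BIN_SIZE",
]

#: PSMC bins the genome into non-overlapping windows of this many sites.
DEFAULT_BIN_SIZE = 100


class PSMCParseError(ValueError):
    pass


@dataclass(frozen=True)
class PSMCRun:
    """One PSMC run: the final-iteration scaled estimates plus the -p label."""

    p_pattern: str
    theta0: float
    rho0: float
    intervals: tuple[tuple[float, float], ...]  # (t_k, lambda_k)
    n_recomb_events: tuple[float, ...]          # per-interval counts

    def __post_init__(self):
        if self.theta0 <= 0:
            raise ValueError("theta0 must be positive")
        t = np.array([iv[0] for iv in self.intervals])
        lam = np.array([iv[1] for iv in self.intervals])
        if len(t) and t[0] != 0.0:
            raise ValueError("first interval must start at t=0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("interval times must be strictly increasing")
        if np.any(lam <= 0):
            raise ValueError("lambda_k must be positive")

    def selection_score(self, criterion: str = "min_per_interval") -> float:
        """Scalar run-selection score from the per-interval recombination counts.

        ``min_per_interval`` (default) maximises the worst-resolved interval;
        ``total`` uses the run-wide sum.
        """
        if not self.n_recomb_events:
            return 0.0
        if criterion == "min_per_interval":
            return float(min(self.n_recomb_events))
        if criterion == "total":
            return float(sum(self.n_recomb_events))
        raise ValueError(f"unknown criterion {criterion!r}")


def _finalize_block(block: dict, runs: list[PSMCRun], line_no: int) -> None:
    if block.get("theta0") is None:
        raise PSMCParseError(f"block ending at line {line_no}: missing TR line")
    if not block["rs"]:
        raise PSMCParseError(f"block ending at line {line_no}: missing RS lines")
    runs.append(
        PSMCRun(
            p_pattern=block.get("pa", ""),
            theta0=block["theta0"],
            rho0=block.get("rho0", 0.0),
            intervals=tuple((t, lam) for t, lam, _ in block["rs"]),
            n_recomb_events=tuple(c for _, _, c in block["rs"]),
        )
    )


def parse_psmc_output(stream: str) -> list[PSMCRun]:
    """Parse PSMC-format text into one :class:`PSMCRun` per run.

    Each run's FINAL iteration block provides theta0 (TR line), the atomic
    intervals (RS lines: index, t_k, lambda_k and, when present, a 4th
    numeric column read as the per-interval recombination-event count) and
    the -p pattern (PA line).
    """
    if not stream.strip():
        raise PSMCParseError("empty PSMC stream")
    # blocks separated by '//'; group into runs on round-counter reset
    blocks: list[tuple[int, dict]] = []
    cur: dict | None = None
    for i, raw in enumerate(stream.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tag, _, rest = line.partition("\t")
        if tag == line:  # allow space-separated dialects
            parts = line.split(None, 1)
            tag = parts[0]
            rest = parts[1] if len(parts) > 1 else ""
        if tag == "RD":
            cur = {"rd": int(rest.split()[0]), "theta0": None, "rho0": 0.0,
                   "rs": [], "pa": "", "end": i}
            blocks.append((i, cur))
        elif tag == "//":
            cur = None
        elif cur is None:
            continue  # header lines (CC, MM) before any RD
        elif tag == "TR":
            vals = rest.split()
            if len(vals) < 2:
                raise PSMCParseError(f"line {i}: malformed TR line")
            cur["theta0"], cur["rho0"] = float(vals[0]), float(vals[1])
        elif tag == "RS":
            vals = rest.split()
            if len(vals) < 3:
                raise PSMCParseError(f"line {i}: malformed RS line")
            t_k, lam = float(vals[1]), float(vals[2])
            n_rec = float(vals[3]) if len(vals) > 3 else 0.0
            cur["rs"].append((t_k, lam, n_rec))
            cur["end"] = i
        elif tag == "PA":
            cur["pa"] = rest.split()[0] if rest.split() else ""
            cur["end"] = i
    if not blocks:
        raise PSMCParseError("no RD blocks found in stream")
    # split into runs where the round counter resets
    runs: list[PSMCRun] = []
    run_blocks: list[tuple[int, dict]] = []
    last_rd = None
    for start, blk in blocks:
        if last_rd is not None and blk["rd"] <= last_rd:
            _finalize_block(run_blocks[-1][1], runs, run_blocks[-1][1]["end"])
            run_blocks = []
        run_blocks.append((start, blk))
        last_rd = blk["rd"]
    _finalize_block(run_blocks[-1][1], runs, run_blocks[-1][1]["end"])
    return runs


def read_psmc(path) -> list[PSMCRun]:
    with open(path) as fh:
        return parse_psmc_output(fh.read())


def write_psmc(runs, path_or_buf) -> None:
    """Write runs in the PSMC text dialect (round-trips through the parser).

    Each run is written as two iteration blocks (a round-0 placeholder and
    the final round) so consumers exercise final-block selection.
    """
    if isinstance(runs, PSMCRun):
        runs = [runs]
    lines = []
    for run in runs:
        for rd in (0, 25):
            lines.append(f"RD\t{rd}")
            lines.append(f"TR\t{run.theta0:.10g}\t{run.rho0:.10g}")
            for k, (t_k, lam) in enumerate(run.intervals):
                n_rec = run.n_recomb_events[k] if k < len(run.n_recomb_events) else 0.0
                if rd == 0:  # placeholder round: perturbed values, must be ignored
                    lam = 1.0
                lines.append(f"RS\t{k}\t{t_k:.10g}\t{lam:.10g}\t{n_rec:.10g}")
            lines.append(f"PA\t{run.p_pattern}")
            lines.append("//")
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def select_run(runs: list[PSMCRun], criterion: str = "min_per_interval") -> PSMCRun:
    """Pick the run maximising the recombination-event criterion.

    Ties break to the first occurrence, so selection is deterministic.
    """
    if not runs:
        raise ValueError("no runs to select from")
    scores = [r.selection_score(criterion) for r in runs]
    return runs[int(np.argmax(scores))]


def scale_to_real_units(run: PSMCRun, mu: float, gen_time_yr: float,
                        bin_size: int = DEFAULT_BIN_SIZE,
                        species_id: str = "unknown") -> NeTrajectory:
    """Convert scaled PSMC estimates to diploid Ne vs years before present.

    N0 = theta0 / (4 * mu * bin_size); ne_k = N0 * lambda_k;
    boundary_k = 2 * N0 * t_k * gen_time_yr.  The terminal (oldest) boundary
    closes the last interval by continuing the run's own log-spaced grid one
    step (ratio of the last two interval starts); no values are extrapolated.
    """
    if mu <= 0 or gen_time_yr <= 0 or bin_size <= 0:
        raise ValueError("mu, gen_time_yr and bin_size must be positive")
    n0 = run.theta0 / (4.0 * mu * bin_size)
    t = np.array([iv[0] for iv in run.intervals])
    lam = np.array([iv[1] for iv in run.intervals])
    boundaries_yr = 2.0 * n0 * t * gen_time_yr
    if len(t) >= 3 and t[-2] > 0:
        top = boundaries_yr[-1] * (t[-1] / t[-2])
    else:
        top = boundaries_yr[-1] * 2.0
    boundaries = np.append(boundaries_yr, top)
    return NeTrajectory(species_id, boundaries, n0 * lam)


def trajectory_to_run(traj: NeTrajectory, mu: float, gen_time_yr: float,
                      bin_size: int = DEFAULT_BIN_SIZE,
                      p_pattern: str = "4+25*2+4+6",
                      n_recomb_events=None) -> PSMCRun:
    """Inverse of :func:`scale_to_real_units` (N0 taken as the youngest Ne).

    Used by the synthetic-data generator to emit PSMC-format fixtures whose
    parse-and-rescale round trip reproduces the trajectory exactly.
    """
    if mu <= 0 or gen_time_yr <= 0 or bin_size <= 0:
        raise ValueError("mu, gen_time_yr and bin_size must be positive")
    if traj.boundaries[0] != 0.0:
        raise ValueError("trajectory must start at 0 yr BP to encode as PSMC")
    n0 = float(traj.ne[0])
    theta0 = 4.0 * mu * bin_size * n0
    t = traj.boundaries[:-1] / (2.0 * n0 * gen_time_yr)
    lam = traj.ne / n0
    if n_recomb_events is None:
        n_recomb_events = tuple(100.0 for _ in lam)
    return PSMCRun(
        p_pattern=p_pattern, theta0=theta0, rho0=theta0 / 5.0,
        intervals=tuple(zip(t.tolist(), lam.tolist())),
        n_recomb_events=tuple(n_recomb_events),
    )
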
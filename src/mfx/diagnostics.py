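"""Run provenance and the per-stage sequence-count ledger.

Every pipeline invocation is recorded as a RunRecord (command, parameters,
timestamps, input content digests, external tool versions) in a file-backed
store, and each stage appends the number of sequences still under
consideration.  The stage report reproduces the shape of a matrix-
construction funnel: counts and deltas from cataloging through homology
clustering, alignment refinement, ortholog pruning, and concatenation.
Reports are CSV/JSON plus an optional static plot; no HTML.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import os
import shutil
import subprocess
from dataclasses import asdict, dataclass, field

import pandas as pd

from .seqio import StageCount


@dataclass
class RunRecord:
    run_id: str
    command: str
    parameters: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    tool_versions: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    external_calls: list = field(default_factory=list)


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def _sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class RunStore:
    """Append-only run ledger persisted as a single JSON file."""

    def __init__(self, path: str):
        self.path = path
        self._runs: dict[str, RunRecord] = {}
        self._stages: dict[str, list[dict]] = {}
        if os.path.exists(path) and os.path.getsize(path) > 0:
            with open(path) as fh:
                raw = json.load(fh)
            for rid, rec in raw["runs"].items():
                self._runs[rid] = RunRecord(**rec)
            self._stages = raw["stages"]

    def _flush(self) -> None:
        payload = {
            "runs": {rid: asdict(rec) for rid, rec in self._runs.items()},
            "stages": self._stages,
        }
        with open(self.path, "w") as fh:
            json.dump(payload, fh, indent=1)

    # -- runs ---------------------------------------------------------------

    def new_run(
        self,
        command: str,
        parameters: dict | None = None,
        input_paths: list[str] | None = None,
        run_id: str | None = None,
    ) -> RunRecord:
        if run_id is None:
            run_id = f"run{len(self._runs) + 1:04d}"
        if run_id in self._runs:
            raise ValueError(f"run_id {run_id!r} already exists")
        digests = {p: _sha256_file(p) for p in (input_paths or []) if os.path.exists(p)}
        record = RunRecord(
            run_id=run_id,
            command=command,
            parameters=dict(parameters or {}),
            started=_now(),
            input_digests=digests,
        )
        self._runs[run_id] = record
        self._stages[run_id] = []
        self._flush()
        return record

    def finish_run(self, run_id: str) -> None:
        self.get_run(run_id).finished = _now()
        self._flush()

    def get_run(self, run_id: str) -> RunRecord:
        if run_id not in self._runs:
            raise KeyError(f"unknown run_id {run_id!r}")
        return self._runs[run_id]

    def log_external_call(self, run_id: str, argv: list[str], version: str = "") -> None:
        """Record an external-tool invocation: argv, version, binary digest."""
        record = self.get_run(run_id)
        executable = shutil.which(argv[0]) if argv else None
        digest = _sha256_file(executable) if executable else ""
        if not version and executable:
            try:
                out = subprocess.run(
                    [argv[0], "--version"], capture_output=True, text=True, timeout=10
                )
                version = (out.stdout or out.stderr).splitlines()[0] if (out.stdout or out.stderr) else ""
            except Exception:
                version = ""
        record.external_calls.append({"argv": list(argv), "version": version, "binary_sha256": digest})
        if argv:
            record.tool_versions[argv[0]] = version
        self._flush()

    # -- stage ledger -------------------------------------------------------

    def record_stage(
        self, run_id: str, stage_name: str, n_sequences: int, reason: str = ""
    ) -> StageCount:
        if run_id not in self._runs:
            raise KeyError(f"unknown run_id {run_id!r}")
        count = StageCount(run_id=run_id, stage_name=stage_name, n_sequences=n_sequences)
        self._stages[run_id].append(
            {"stage_name": stage_name, "n_sequences": n_sequences, "reason": reason}
        )
        self._flush()
        return count

    def stage_counts(self, run_id: str) -> list[StageCount]:
        """Ordered stage counts; a re-recorded stage name reports its latest value
        at its first-recorded position."""
        if run_id not in self._runs:
            raise KeyError(f"unknown run_id {run_id!r}")
        order: list[str] = []
        latest: dict[str, int] = {}
        for entry in self._stages[run_id]:
            name = entry["stage_name"]
            if name not in latest:
                order.append(name)
            latest[name] = entry["n_sequences"]
        return [StageCount(run_id, name, latest[name]) for name in order]

    def stage_report(self, run_id: str, csv_path: str | None = None) -> pd.DataFrame:
        """Stage table with deltas between consecutive stages.

        Columns: stage_name, n_sequences, delta, delta_reason.  The first
        stage has no delta.
        """
        counts = self.stage_counts(run_id)
        if not counts:
            raise ValueError(f"run {run_id!r}: empty stage ledger")
        reasons: dict[str, str] = {}
        for entry in self._stages[run_id]:
            reasons[entry["stage_name"]] = entry.get("reason", "")
        rows = []
        prev = None
        for sc in counts:
            rows.append(
                {
                    "stage_name": sc.stage_name,
                    "n_sequences": sc.n_sequences,
                    "delta": (sc.n_sequences - prev) if prev is not None else pd.NA,
                    "delta_reason": reasons.get(sc.stage_name, ""),
                }
            )
            prev = sc.n_sequences
        df = pd.DataFrame(rows)
        if csv_path:
            df.to_csv(csv_path, index=False)
        return df

    def plot_stage_counts(self, run_id: str, png_path: str) -> None:
        """Simple static bar chart of sequence counts per stage."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.stage_report(run_id)
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.bar(df["stage_name"], df["n_sequences"], color="#4878a8")
        ax.set_ylabel("sequences under consideration")
        ax.set_xlabel("stage")
        ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
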
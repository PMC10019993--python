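"""Published per-trial movement tables and the report computed from them.

The packaged fixtures transcribe the study's per-trial movement scores
for three animals under the free and the automatically stimulated
condition (nine 7-minute trials each).  ``load_fixture_tables`` verifies
the transcription checksums; ``fixture_report`` recomputes the
per-animal means and the improvement percentages from the trial-level
values.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from roachloop import arena_metrics

__all__ = ["load_fixture_tables", "fixture_report"]

_CHECKSUMS = {
    "free_movement_trials.csv":
        "e83a869ffd02ad3384fd1b47582595b6deefce904468a84a23debf943f26dba3",
    "stimulated_movement_trials.csv":
        "db01162d1ff4703c0254e91b8cf81c2fc05d14eca3a85e3703ea2b95c1f9dce2",
}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("roachloop.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise ValueError(f"fixture {name} failed its transcription checksum")
    from io import BytesIO
    return pd.read_csv(BytesIO(raw))


def load_fixture_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(free, stimulated) per-trial tables: 9 trials × 5 (resp. 6) metrics."""
    free = _read("free_movement_trials.csv")
    stim = _read("stimulated_movement_trials.csv")
    assert len(free) == 9 and len(stim) == 9
    return free, stim


def fixture_report() -> dict:
    """Per-animal means and improvement statistics of the fixture tables."""
    free, stim = load_fixture_tables()
    free_summary = arena_metrics.summarize_trials(free)
    stim_summary = arena_metrics.summarize_trials(stim)
    improvement = arena_metrics.improvement_stats(free_summary, stim_summary)
    return {
        "free_per_animal_means": free_summary.round(4).to_dict(orient="index"),
        "stimulated_per_animal_means": stim_summary.round(4).to_dict(orient="index"),
        "improvement": {
            "per_animal_change_pct": {
                m: {a: round(v, 2) for a, v in d.items()}
                for m, d in improvement["per_animal_change_pct"].items()},
            "mean_change_pct": {m: round(v, 2) for m, v in
                                improvement["mean_change_pct"].items()},
            "pooled_change_pct": {m: round(v, 2) for m, v in
                                  improvement["pooled_change_pct"].items()},
            "headline": improvement["headline"],
        },
    }
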
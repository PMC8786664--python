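#!/usr/bin/env python
"""Natural-abundance correction and enrichment extraction.

Runs the correct stage of the pipeline on the simulated raw MID table and
verifies on the way out that unlabelled (t = 0) measurements correct back to
approximately zero enrichment — the diagnostic the correction is judged by.
"""

from pathlib import Path

from chloroflux.pipeline import RunConfig, run_pipeline
from chloroflux.tablesio import read_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = RunConfig(
        mid_table=str(ROOT / "synthetic" / "mid_table_short_pulse.tsv"),
        pool_table=str(ROOT / "synthetic" / "pool_table.tsv"),
        out_dir=str(ROOT / "02_corrected"), seed=1,
        stages=("correct",))
    run_pipeline(cfg)
    enr = read_table(ROOT / "02_corrected" / "enrichment_long.tsv")
    t0 = enr[enr["time_s"] == 0.0]["enrichment"]
    print(f"corrected {len(enr)} enrichment records")
    print(f"residual apparent enrichment at t=0 after correction: "
          f"mean {t0.mean():.2e}, max {t0.max():.2e}")
    print("(the small positive floor is the non-negativity clip of the "
          "correction acting on measurement noise; downstream estimators "
          "subtract this blank)")


if __name__ == "__main__":
    main()
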
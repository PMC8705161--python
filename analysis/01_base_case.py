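"""Deterministic base case: lifetime two-arm run at the published inputs.

Finding: BNP-guided care is dominant — it saves cost and gains QALYs
relative to standard clinical assessment — matching the published
qualitative conclusion, although the absolute per-arm totals differ from
the printed ones (the publication leaves the cost-accrual and
transition-label semantics unstated; see docs/methods.md).

Writes results/base_case.csv; per-arm cohort traces go to scratch/
(bulky, regenerable).
"""

from pathlib import Path

import pandas as pd

from bnpcea.cea import run_base_case
from bnpcea.engine import run_cohort
from bnpcea.params import Arm, default_bundle

OUT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    bundle = default_bundle()
    res = run_base_case(bundle)
    OUT.mkdir(exist_ok=True)
    pd.DataFrame([{
        "strategy": "BNP", "cost_usd": res.bnp.cost, "qalys": res.bnp.qaly,
        "delta_cost": res.delta_cost, "delta_qaly": res.delta_qaly,
        "classification": res.classification, "nmb_at_20800": res.nmb,
    }, {
        "strategy": "standard", "cost_usd": res.standard.cost, "qalys": res.standard.qaly,
        "delta_cost": None, "delta_qaly": None, "classification": None, "nmb_at_20800": None,
    }]).to_csv(OUT / "base_case.csv", index=False)
    SCRATCH.mkdir(exist_ok=True)
    for arm in Arm:
        run_cohort(arm, bundle).to_frame().to_csv(
            SCRATCH / f"trace_{arm.value.lower()}.csv", index=False
        )
    print(f"BNP:      {res.bnp.cost:8.0f} USD  {res.bnp.qaly:.3f} QALYs")
    print(f"standard: {res.standard.cost:8.0f} USD  {res.standard.qaly:.3f} QALYs")
    print(f"increment: {res.delta_cost:+.0f} USD, {res.delta_qaly:+.3f} QALYs "
          f"-> {res.classification} (NMB {res.nmb:.0f} USD at 20,800/QALY)")


if __name__ == "__main__":
    main()
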
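"""Ground-truth recovery battery at scaled-down problem sizes.

Runs the calibration and recovery experiments that certify the pipeline:
NBS family-wise error under the global null, power on an injected
cluster, dynamic-edge discrimination, PSS-edge recovery, and the exact
GLM / preprocessing oracles.  Identical to what scripts/acceptance.py
reports; kept here so the analysis sequence is self-contained.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from restfc import validation as V  # noqa: E402

RESULTS = ROOT / "results"


def main(seed: int = 22) -> None:
    out = {
        "glm_vs_ttest_max_dev": V.contrast_vs_ttest_max_dev(100, seed),
        "nbs_null_fwer": V.fwer_null_simulation(200, n_perm=500, seed=seed),
        "nbs_power": V.power_recovery_simulation(50, n_perm=500, seed=seed),
        "dfc_discrimination": V.dfc_discrimination_rate(100, seed=seed),
        "pss_recovery": V.association_recovery_rate(50, seed=seed),
        "compcor_subspace_angle": V.compcor_subspace_angle(seed=seed),
        "rms_oracle_dev": V.rms_motion_oracle_dev(seed=seed),
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "validation_battery.json").write_text(json.dumps(out, indent=1))
    print(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
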
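"""Preprocess every subject and build static and dynamic connectomes.

Runs the per-subject chain (drop 4 frames, 0.008 Hz cosine high-pass,
motion + 5+5 CompCor nuisance regression, variance normalization), then
the Fisher-z static matrix and the fixed ~34 s sliding-window
temporal-variability matrix.  Connectomes land in scratch (one TSV per
subject); a small summary goes to results/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import numpy as np  # noqa: E402

from restfc import io as rio  # noqa: E402
from restfc.connectome import dynamic_fc, static_fc, window_lengths  # noqa: E402
from restfc.preprocess import preprocess_subject  # noqa: E402
from restfc.synthetic import generate_motion_and_compartments  # noqa: E402

SCRATCH = ROOT / "scratch" / "cohort_run"
RESULTS = ROOT / "results"


def main() -> None:
    from importlib import import_module

    sim = import_module("01_simulate_cohort")
    cfg = sim.main()  # regenerates deterministically if scratch was cleaned

    cohort_dir = SCRATCH / "cohort"
    subjects = rio.read_subject_table(cohort_dir / "subjects.csv")
    cc = __import__("restfc.synthetic", fromlist=["CohortConfig"]).CohortConfig(
        n_per_group=cfg.n_per_group, n_roi=cfg.n_roi, n_frames=cfg.n_frames,
        effect_edges=cfg.effect_edges, static_effect_delta=cfg.static_effect_delta,
        dynamic_effect_amp=cfg.dynamic_effect_amp,
        dynamic_effect_edges=cfg.dynamic_effect_edges, pss_edges=cfg.pss_edges,
        seed=cfg.seed,
    )
    motion, wm, csf, _ = generate_motion_and_compartments(cc)

    conn = SCRATCH / "connectomes"
    conn.mkdir(exist_ok=True)
    win_secs, rms = [], []
    for k, sub in enumerate(subjects):
        ts = rio.read_roi_timeseries(cohort_dir / f"{sub.subject_id}_roi.tsv")
        clean = preprocess_subject(ts, motion[k], wm[k], csf[k])
        sfc = static_fc(clean)
        dfc = dynamic_fc(clean, window_lengths(clean, "fixed"))
        rio.write_connectivity(sfc, conn / f"{sub.subject_id}_sfc_z.tsv")
        rio.write_connectivity(dfc, conn / f"{sub.subject_id}_dfc_sd.tsv")
        win_secs.append(dfc.meta["mean_window_seconds"])
        rms.append(sub.rms_motion_mm)

    summary = {
        "n_subjects": len(subjects),
        "n_edges": int(cfg.n_roi * (cfg.n_roi - 1) / 2),
        "mean_window_seconds": float(np.mean(win_secs)),
        "rms_motion_mean_mm": float(np.mean(rms)),
        "rms_motion_max_mm": float(np.max(rms)),
    }
    (RESULTS / "connectome_summary.json").write_text(json.dumps(summary, indent=1))
    print("connectome summary:", summary)


if __name__ == "__main__":
    main()
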
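"""Cost every hospital stay in 2018 euros.

Initial stays are valued with the adjusted-DRG method (micro-costed theatre
cost of the randomised procedure plus the catalog per-diem times the
patient's LOS); re-hospitalisations are gross-costed at their DRG catalog
total; rehabilitation admissions carry the flat cost of their single DRG.
Writes results/trial/stays_costed.csv.
"""
import argparse
import warnings

import numpy as np

from thoracic_cea import pipeline, synthetic_trial


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--trial-dir", default="results/trial")
    args = ap.parse_args()

    patients_df = pipeline.load_patients(f"{args.trial_dir}/patients.csv")
    stays = pipeline.load_stays(f"{args.trial_dir}/stays.csv")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", UserWarning)
        stays = pipeline.stage_cost(stays, patients_df)
    uncostable = sum("could not be costed" in str(w.message) for w in caught)

    frame = synthetic_trial.stays_frame(stays)
    frame.to_csv(f"{args.trial_dir}/stays_costed.csv", index=False)

    arm = dict(zip(patients_df.patient_id, patients_df.arm))
    initial = frame[frame.stay_type == "initial"].assign(
        arm=lambda d: d.patient_id.map(arm)
    )
    means = initial.groupby("arm").cost.mean().round(0).astype(int).to_dict()
    print(f"costed {frame.cost.notna().sum()} of {len(frame)} stays "
          f"({uncostable} uncostable, excluded with warnings)")
    print(f"mean initial-stay cost by arm (EUR 2018): {means}")
    rehab = frame[frame.stay_type == 'rehabilitation'].cost
    if len(rehab):
        assert (np.isclose(rehab, 6222.20)).all()
        print(f"{len(rehab)} rehabilitation stays at the flat 6222.20 EUR")
    print(f"wrote {args.trial_dir}/stays_costed.csv")


if __name__ == "__main__":
    main()
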
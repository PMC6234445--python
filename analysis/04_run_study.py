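"""Run the full age-comparison airflow study (3 ages x 2 phases).

Steady laminar solves on the G6-G9 trees with the tabulated breathing
parameters, followed by post-processing into the cross-age report with
published-value comparison columns and monotonicity flags.

Artifacts land under results/study/ (per-case surfaces, meshes, fields,
section tables, and the top-level report.csv / report.json).
"""

import logging
from pathlib import Path

from airwaycfd import study_pipeline as SP

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    config = SP.StudyConfig(
        output_dir=str(ROOT / "results" / "study"),
        mesh_size_fraction=0.25,
        n_layers=1,
        seed=1,
    )
    report = SP.run_study(config)
    print(report.table.to_string(index=False))
    print("\nmonotonicity checks:")
    for key, ok in sorted(report.monotonicity.items()):
        print(f"  {key}: {'yes' if ok else 'NO'}")
    verdict = SP.acceptance_harness(report)
    verdict.to_csv(ROOT / "results" / "acceptance_verdict.csv", index=False)
    print("\nacceptance harness:")
    print(verdict.to_string(index=False))


if __name__ == "__main__":
    main()
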
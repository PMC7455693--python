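"""Write a synthetic fixture set in the pipeline's external formats.

Generates a small cohort and serialises it exactly as the pipeline reads
it: a merged abundance TSV, sample metadata, subject grades, per-species
nGD matrices and a manifest recording the seed and parameters.  The same
directory feeds `fmtrack run-all --fixture DIR`.
"""

import json
import tempfile
from pathlib import Path

from fmtrack import SimParams, simulate_cohort, write_fixture_set


def main():
    out = Path(tempfile.mkdtemp(prefix="fmtrack_fixture_"))
    cohort = simulate_cohort(SimParams(n_species=40, seed=1))
    manifest = write_fixture_set(cohort, out)

    print(f"fixture directory: {out}")
    for key, value in manifest["files"].items():
        if isinstance(value, list):
            print(f"  {key}: {len(value)} files under strains/")
        else:
            print(f"  {key}: {value}")
    print(f"  seed: {manifest['seed']}")
    print()
    print("ground_truth.tsv holds the planted per-(patient, species, visit)")
    print("labels, so any downstream classification can be scored exactly.")
    print(f"next: fmtrack run-all --fixture {out} --out {out / 'bundle'}")


if __name__ == "__main__":
    main()
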
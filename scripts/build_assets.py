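"""Regenerate the packaged data assets deterministically.

Creates, from the synthetic structure library:
* the default 17-state structural alphabet (Gaussian mixture over embedded
  angle triplets), and
* the Cα pair-distance reference distributions used by the stand-in
  potential, one per binning variant.

Run from the repository root:  python scripts/build_assets.py
"""

import json
from pathlib import Path

from pwcom.features import _STANDIN_VARIANTS, compute_reference_distribution
from pwcom.structcode import fit_state_model
from pwcom.synthetic import training_library

DATA = Path(__file__).resolve().parent.parent / "src" / "pwcom" / "data"
SEED = 977  # library seed; alphabet fit re-seeds below


def main() -> None:
    DATA.mkdir(exist_ok=True)
    library = training_library(n=40, L=80, seed=SEED)

    model = fit_state_model(library, K=17, seed=0)
    model.to_json(DATA / "default_state_model.json")
    print(f"state model: K={model.K}, {len(library)} training traces")

    ref = {}
    for name, params in _STANDIN_VARIANTS.items():
        key = f"{params['bin_width']:g}_{params['r_max']:g}_{params['min_sep']}"
        if key not in ref:
            ref[key] = compute_reference_distribution(library, **params).tolist()
    (DATA / "ca_distance_reference.json").write_text(json.dumps(ref, indent=1))
    print(f"distance reference: variants {sorted(ref)}")


if __name__ == "__main__":
    main()
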
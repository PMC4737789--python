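"""Build the packaged default discriminant model.

Trains the full + reduced discriminants and the spectral PCA on a
fixed-seed simulated audio cohort (40 healthy / 40 diseased, 30 s
recordings) and writes src/cadscore/data/default_model.json so the CLI
scores recordings out of the box.  Re-run after changing the simulator or
the feature pipeline:

    python scripts/build_default_model.py
"""

import json
from pathlib import Path

from cadscore.scoring import train_discriminant
from cadscore.simulator import AudioCohortParams, simulate_audio_cohort
from cadscore.spectral_features import extract_cohort_features

SEED = 20150903
OUT = Path(__file__).resolve().parents[1] / "src" / "cadscore" / "data" / "default_model.json"


def main() -> None:
    recs, labels, _ = simulate_audio_cohort(
        AudioCohortParams(n_healthy=40, n_diseased=40, seed=SEED), duration_s=30.0
    )
    features, pca = extract_cohort_features(recs)
    model = train_discriminant(features, labels)
    payload = json.loads(model.to_json())
    payload["metadata"]["training"] = (
        f"simulated audio cohort, 40+40 subjects, 30 s recordings, seed {SEED}"
    )
    payload["pca"] = pca.to_dict()
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(payload, indent=2) + "\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
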
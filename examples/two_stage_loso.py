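"""The full two-stage study at desk scale.

Generates a 12-subject noisy synthetic study where motion is the only
class signal, then runs leave-one-subject-out cross-validation of the
two-stage pipeline: Model 1 trained on all stacked frames, Top-20
confidence-based frame selection, Model 2 retrained on the curated
frames, both evaluated on every frame of the held-out subject's videos
and aggregated to video labels by average pooling.
"""

from painpipe import cross_validate_embeddings, handles_from_dataset, generate_dataset
from painpipe.pipeline import prepare_frames
from painpipe.presets import SCALED_N_VAL, scaled_pipeline_config, scaled_study_config

SEED = 0

config = scaled_study_config(SEED)
dataset = generate_dataset(config)
print(f"study: {config.n_subjects} subjects x 2 videos, {config.duration_s:.0f} s @ {config.fps:.0f} fps")

for grayst in (True, False):
    pipeline = scaled_pipeline_config(grayst_enabled=grayst)
    embeddings, counts = prepare_frames(handles_from_dataset(dataset), pipeline)
    result = cross_validate_embeddings(embeddings, pipeline, n_val=SCALED_N_VAL, seed=SEED)
    mode = "GrayST" if grayst else "RGB   "
    print(f"\n[{mode}] frames: sampled={counts['sampled']} "
          f"dropped={counts['dropped_no_detection']} embedded={counts['embedded']}")
    for model in ("model1", "model2"):
        m = result[model].metrics()
        print(f"  {model}: video accuracy {m['video']['accuracy']:.3f} "
              f"(precision {m['video']['precision']:.3f}, recall {m['video']['recall']:.3f}) | "
              f"frame accuracy {m['frame']['accuracy']:.3f}")

print(
    "\nGrayST (motion made visible) far outperforms plain RGB frames when "
    "the classes differ only in movement; retraining on the Top-20 curated "
    "frames (Model 2) matches or improves the naive Model 1."
)
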
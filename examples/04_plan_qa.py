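"""Use trained models to QA a new plan.

Trains on a small cohort, serializes the models to JSON, reloads them,
and checks a held-out plan: an organ is flagged when the planned
D2cm3/Dprescription deviates from the model's anatomy-based prediction
by more than a delta threshold, suggesting the plan (not the anatomy)
is the outlier and may deserve re-optimization.
"""

from pathlib import Path
import tempfile

from brachyqa.model import SVRConfig, load_model, save_model
from brachyqa.phantom import PhantomConfig, generate_plan
from brachyqa.pipeline import FEATURE_COLS, qa_check, run_experiment, simulate_cohort
from brachyqa.structures import OAR_NAMES

cfg = PhantomConfig(n_plans=60)
frame = simulate_cohort(cfg)
result = run_experiment(frame, SVRConfig(seed=0), n_train=48, n_valid=12)

# Round-trip the models through JSON, as the CLI does.
tmp = Path(tempfile.mkdtemp())
models = {}
for organ, m in result.models.items():
    save_model(m, tmp / f"model_{organ}.json")
    models[organ] = load_model(tmp / f"model_{organ}.json")

# A "new" plan: index 61 was never part of the 60-plan cohort above.
rec = generate_plan(cfg, plan_index=61)
features = {o: rec.features[o].values for o in OAR_NAMES}
actual = rec.metrics.ratio

verdicts = qa_check(models, features, actual, delta_threshold=0.10)
print("organ             actual  predicted   delta   verdict")
for organ, v in verdicts.items():
    print(
        f"{organ:16s}  {v['actual_ratio']:.4f}   {v['predicted_ratio']:.4f}"
        f"   {v['delta']:.4f}   {v['verdict']}"
    )

# A consistent plan passes everywhere. Simulate a planning error by
# inflating the bladder dose 30% and re-checking:
actual_bad = dict(actual)
actual_bad["bladder"] *= 1.3
flagged = qa_check(models, features, actual_bad, delta_threshold=0.10)
print(f"\nafter +30% bladder dose: bladder -> {flagged['bladder']['verdict']}")
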
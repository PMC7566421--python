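"""Interval scaling: turning uneven visit times into feature weights.

Each visit at time t_i is weighted by w_i = 1/(t_pred - t_i).  Visits
closer to the prediction horizon get larger weights, so the model
leans on recent images without assuming evenly spaced follow-up.
"""

import numpy as np

from fundusgru import apply_scaling, interval_weights

times = [0.0, 14.0, 21.0]      # months; note the uneven gaps
t_pred = 33.0                  # when the outcome is to be predicted

w = interval_weights(times, t_pred)
print(f"visit times (months):      {times}")
print(f"prediction horizon:        {t_pred}")
print(f"interval weights 1/(tp-t): {np.round(w.weights, 4)}")
print("The last visit (12 months before the horizon) weighs "
      f"{w.weights[-1] / w.weights[0]:.1f}x the first (33 months before).")

features = np.ones((3, 4))     # toy 3-visit x 4-feature matrix
scaled = apply_scaling(features, w)
print("\nscaled rows of an all-ones feature matrix:")
print(np.round(scaled, 4))

# pushing the horizon further out shrinks and flattens the weights:
far = interval_weights(times, 57.0)
print(f"\nsame visits, horizon 57 months: {np.round(far.weights, 4)} "
      "(longer-range forecasts weigh all visits more evenly)")
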
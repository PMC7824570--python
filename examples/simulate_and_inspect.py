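"""Simulate one joint longitudinal-survival dataset and look inside it.

Subjects carry a binary group indicator, Gaussian random intercepts/slopes,
an event time drawn by inverse-transform sampling from the closed-form
survival function, uniform censoring on (0, t_max), and noisy equispaced
measurements of their trajectory up to the observed time.
"""

from twostagejm import SimulationConfig, default_truth, simulate_dataset
from twostagejm.io import write_joint_dataset

cfg = SimulationConfig(truth=default_truth(), n=200, m_min=3, t_max=15.0, seed=42)
data = simulate_dataset(cfg)

print(f"subjects: {data.n}, event rate: {data.event_rate:.3f}")
s = data.subjects[0]
print(f"subject {s.id}: group x={s.x}, observed time T={s.T:.3f}, event={s.delta}")
print(f"  {len(s.times)} measurements at t = {[round(float(t), 2) for t in s.times]}")
print(f"  y = {[round(float(v), 3) for v in s.y]}")
# the event rate (~2/3 here) reflects how often the latent event time beats
# the uniform censoring draw; longer survivors carry more measurements

write_joint_dataset(data, "longitudinal.csv", "survival.csv")
print("wrote longitudinal.csv and survival.csv")
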
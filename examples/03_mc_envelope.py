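"""Propagate parameter precision into a simulation uncertainty band.

Thirty Monte Carlo draws perturb (vmax, Km per NTP) within their
determination standard errors; each draw is simulated and the pointwise
min/max forms the envelope.  Draw 0 is the nominal set, so the band is
guaranteed to contain the nominal trajectory.
"""

import numpy as np

import ivtwin as iv

params = iv.synthetic.reference_params()
dist = iv.ParamDistribution(
    mean=params,
    vmax_se=0.001,
    Km_se={"A": 2.9, "C": 1.9, "G": 6.4, "U": 3.8},
)
init = iv.ReactionState(t=0.0, c_NTP={b: 10000.0 for b in iv.BASES})
band = iv.mc_envelope(
    init, dist, iv.PPiaseParams.default(), iv.synthetic.bnt_like_transcript(),
    np.linspace(0.0, 40.0, 21), n=30, seed=1,
)

b = band.band("c_mRNA_uM")
print("t_min  lower  nominal  upper   (mRNA, uM)")
for i in range(0, len(b), 4):
    row = b.iloc[i]
    nom = band.nominal["c_mRNA_uM"][i]
    print(f"{row['t_min']:5.0f}  {row['lower']:6.3f}  {nom:7.3f}  {row['upper']:6.3f}")
print()
print(f"peak band width: {band.width('c_mRNA_uM').max():.4f} uM "
      f"({band.n_draws} draws, seed {band.seed})")
print("the width shows how far the fitted-parameter precision moves the")
print("predicted transient; the late plateau is stoichiometric and tight.")
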
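"""Predict one woman's probability of skilled birth attendance.

The model is P(SBA) = 1 - Gk(t)·F(d): she delivers unattended only if
her labour starts before her planned move to the maternity waiting
home (probability F(d)) AND her latent phase is shorter than her
travel time to care (probability Gk(t)).
"""

import sbarisk as sk

F = sk.onset_distribution("khambalia")          # labour-onset offset CDF, days
G = sk.latent_distribution("multiparous")       # latent-phase CDF, hours

# A multiparous woman 10 h 15 min from skilled care, planning to move
# to the MWH two weeks before her due date.
scenario = sk.Scenario("multiparous", access_time_t=10.25, move_date_d=-14.0)
est = sk.p_sba(scenario, F, G)

print(f"Gk(t = 10.25 h) = {est.gk_of_t:.4f}   (chance her latent phase is shorter than the trip)")
print(f"F(d = -14 d)    = {est.f_of_d:.4f}   (chance labour starts before the move)")
print(f"P(SBA)          = {est.p_sba:.4f}   -> {est.category}")
print()
print("Without any MWH stay the onset factor is 1 and only the trip matters:")
none = sk.p_sba(sk.Scenario("multiparous", 10.25, sk.NO_MWH), F, G)
print(f"P(SBA) = {none.p_sba:.4f}   -> {none.category}")
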
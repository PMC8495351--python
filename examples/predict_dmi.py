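"""Predict the dry-matter intake of one cow with each published equation.

A 640-kg multiparous Holstein in week 20 of lactation, giving 33 kg/d of
3.8%-fat milk on a 33.4%-NDF ration.  Each equation prints its predicted DMI
in kg of feed dry matter per day; the spread between models (~2 kg/d) is
typical of empirical intake equations.
"""

from dmintake import (
    CowState,
    DietComposition,
    predict_cncps,
    predict_jfs,
    predict_kfsd,
    predict_nrc,
)

cow = CowState(bw=640, my=33.0, fat_pct=3.8, wol=20, parity="multiparous")
diet = DietComposition(ndf_pct=33.4, cp_pct=16.9, fpdm_pct=53.0)

print(f"cow: BW {cow.bw} kg (MBW {cow.mbw:.1f}), FCM {cow.fcm:.1f} kg/d, "
      f"week {cow.wol:.0f} of lactation")
print(f"KFSD   : {predict_kfsd(cow, diet):6.2f} kg/d")
print(f"  +lag : {predict_kfsd(cow, diet, apply_lag=True):6.2f} kg/d "
      "(early-lactation depression, negligible by week 20)")
print(f"NRC    : {predict_nrc(cow):6.2f} kg/d")
print(f"CNCPS  : {predict_cncps(cow):6.2f} kg/d")
print(f"JFS    : {predict_jfs(cow):6.2f} kg/d")
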
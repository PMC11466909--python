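"""Generated closed-form focal values for a planar quadratic vector field.

For the system  du/dt = v + p20 u^2 + p11 u v + p02 v^2,
                dv/dt = -Delta u + q20 u^2 + q11 u v + q02 v^2   (Delta > 0),
a Lyapunov function V = (Delta u^2 + v^2)/2 + V3 + V4 + ... can be chosen so
that dV/dt = eta1 (Delta u^2+v^2)^2 + eta2 (.)^3 + eta3 (.)^4 + O(10).  The
sign of the first nonzero eta_k decides the stability of the weak focus, so
eta1, eta2, eta3 play the role of the focal values L1, L2, L3 (eta_{k+1} is
meaningful where eta_1..eta_k vanish).  These expressions were generated by
:func:`crnbif.hopf.derive_focal_values`, which re-derives and checks them in
the test-suite; they are written with plain arithmetic so they can be
evaluated over Fractions, quadratic-field elements, or sympy expressions.
"""

# fmt: off
def eta1(Delta, p20, p11, p02, q20, q11, q02):
    num = (-Delta**2*p02*p11 - 2*Delta**2*p02*q02 - Delta*p11*p20 + Delta*q02*q11 + 2*p20*q20 + q11*q20)
    return num / (8*Delta**2)

def eta2(Delta, p20, p11, p02, q20, q11, q02):
    num = (10*Delta**5*p02**3*p11 + 20*Delta**5*p02**3*q02 + 124*Delta**4*p02**2*p11*p20 + 37*Delta**4*p02**2*p11*q11 + 228*Delta**4*p02**2*p20*q02 + 64*Delta**4*p02**2*q02*q11 - Delta**4*p02*p11**3 + 39*Delta**4*p02*p11**2*q02 + 158*Delta**4*p02*p11*q02**2 + 152*Delta**4*p02*q02**3 - 60*Delta**3*p02**2*p20*q20 - 30*Delta**3*p02**2*q11*q20 + 29*Delta**3*p02*p11**2*q20 + 238*Delta**3*p02*p11*p20**2 + 138*Delta**3*p02*p11*p20*q11 + 136*Delta**3*p02*p11*q02*q20 + 27*Delta**3*p02*p11*q11**2 + 288*Delta**3*p02*p20**2*q02 + 68*Delta**3*p02*p20*q02*q11 + 156*Delta**3*p02*q02**2*q20 - 3*Delta**3*p02*q02*q11**2 - Delta**3*p11**3*p20 + 37*Delta**3*p11**2*p20*q02 - 3*Delta**3*p11**2*q02*q11 + 96*Delta**3*p11*p20*q02**2 - 29*Delta**3*p11*q02**2*q11 - 24*Delta**3*p20*q02**3 - 76*Delta**3*q02**3*q11 + 30*Delta**2*p02*p11*q20**2 - 252*Delta**2*p02*p20**2*q20 - 232*Delta**2*p02*p20*q11*q20 + 60*Delta**2*p02*q02*q20**2 - 53*Delta**2*p02*q11**2*q20 + 27*Delta**2*p11**2*p20*q20 - 3*Delta**2*p11**2*q11*q20 + 124*Delta**2*p11*p20**3 + 101*Delta**2*p11*p20**2*q11 + 28*Delta**2*p11*p20*q02*q20 + 27*Delta**2*p11*p20*q11**2 - 42*Delta**2*p11*q02*q11*q20 + 24*Delta**2*p20**3*q02 - 144*Delta**2*p20**2*q02*q11 - 192*Delta**2*p20*q02**2*q20 - 109*Delta**2*p20*q02*q11**2 - 142*Delta**2*q02**2*q11*q20 - 23*Delta**2*q02*q11**3 - 16*Delta*p11*p20*q20**2 - 13*Delta*p11*q11*q20**2 - 248*Delta*p20**3*q20 - 350*Delta*p20**2*q11*q20 - 132*Delta*p20*q02*q20**2 - 159*Delta*p20*q11**2*q20 - 76*Delta*q02*q11*q20**2 - 23*Delta*q11**3*q20 - 20*p20*q20**3 - 10*q11*q20**3)
    return num / (192*Delta**5)

def eta3(Delta, p20, p11, p02, q20, q11, q02):
    num = (1850*Delta**8*p02**5*p11 + 3700*Delta**8*p02**5*q02 - 5302*Delta**7*p02**4*p11*p20 - 2296*Delta**7*p02**4*p11*q11 - 14304*Delta**7*p02**4*p20*q02 - 6442*Delta**7*p02**4*q02*q11 + 3743*Delta**7*p02**3*p11**3 + 11242*Delta**7*p02**3*p11**2*q02 + 13712*Delta**7*p02**3*p11*q02**2 + 12400*Delta**7*p02**3*q02**3 - 1860*Delta**6*p02**4*p20*q20 - 930*Delta**6*p02**4*q11*q20 - 2880*Delta**6*p02**3*p11**2*q20 - 90984*Delta**6*p02**3*p11*p20**2 - 67288*Delta**6*p02**3*p11*p20*q11 - 13160*Delta**6*p02**3*p11*q02*q20 - 14553*Delta**6*p02**3*p11*q11**2 - 169504*Delta**6*p02**3*p20**2*q02 - 121912*Delta**6*p02**3*p20*q02*q11 - 14800*Delta**6*p02**3*q02**2*q20 - 25890*Delta**6*p02**3*q02*q11**2 + 13593*Delta**6*p02**2*p11**3*p20 + 3094*Delta**6*p02**2*p11**3*q11 - 8356*Delta**6*p02**2*p11**2*p20*q02 - 5679*Delta**6*p02**2*p11**2*q02*q11 - 120656*Delta**6*p02**2*p11*p20*q02**2 - 49232*Delta**6*p02**2*p11*q02**2*q11 - 122784*Delta**6*p02**2*p20*q02**3 - 62816*Delta**6*p02**2*q02**3*q11 - 11*Delta**6*p02*p11**5 - 664*Delta**6*p02*p11**4*q02 - 13845*Delta**6*p02*p11**3*q02**2 - 64906*Delta**6*p02*p11**2*q02**3 - 113402*Delta**6*p02*p11*q02**4 - 67668*Delta**6*p02*q02**5 - 7300*Delta**5*p02**3*p11*q20**2 + 40384*Delta**5*p02**3*p20**2*q20 + 35624*Delta**5*p02**3*p20*q11*q20 - 14600*Delta**5*p02**3*q02*q20**2 + 7716*Delta**5*p02**3*q11**2*q20 - 44602*Delta**5*p02**2*p11**2*p20*q20 - 13315*Delta**5*p02**2*p11**2*q11*q20 - 243456*Delta**5*p02**2*p11*p20**3 - 264096*Delta**5*p02**2*p11*p20**2*q11 - 156056*Delta**5*p02**2*p11*p20*q02*q20 - 104279*Delta**5*p02**2*p11*p20*q11**2 - 50104*Delta**5*p02**2*p11*q02*q11*q20 - 14230*Delta**5*p02**2*p11*q11**3 - 345328*Delta**5*p02**2*p20**3*q02 - 310336*Delta**5*p02**2*p20**2*q02*q11 - 152944*Delta**5*p02**2*p20*q02**2*q20 - 96920*Delta**5*p02**2*p20*q02*q11**2 - 56568*Delta**5*p02**2*q02**2*q11*q20 - 9407*Delta**5*p02**2*q02*q11**3 - 426*Delta**5*p02*p11**4*q20 + 15421*Delta**5*p02*p11**3*p20**2 + 4976*Delta**5*p02*p11**3*p20*q11 - 14074*Delta**5*p02*p11**3*q02*q20 - 570*Delta**5*p02*p11**3*q11**2 - 71382*Delta**5*p02*p11**2*p20**2*q02 - 54486*Delta**5*p02*p11**2*p20*q02*q11 - 81368*Delta**5*p02*p11**2*q02**2*q20 - 14824*Delta**5*p02*p11**2*q02*q11**2 - 282540*Delta**5*p02*p11*p20**2*q02**2 - 184664*Delta**5*p02*p11*p20*q02**2*q11 - 170816*Delta**5*p02*p11*q02**3*q20 - 34205*Delta**5*p02*p11*q02**2*q11**2 - 188408*Delta**5*p02*p20**2*q02**3 - 111040*Delta**5*p02*p20*q02**3*q11 - 121936*Delta**5*p02*q02**4*q20 - 5350*Delta**5*p02*q02**3*q11**2 - 11*Delta**5*p11**5*p20 - 542*Delta**5*p11**4*p20*q02 + 111*Delta**5*p11**4*q02*q11 - 11689*Delta**5*p11**3*p20*q02**2 + 1714*Delta**5*p11**3*q02**2*q11 - 43772*Delta**5*p11**2*p20*q02**3 + 10717*Delta**5*p11**2*q02**3*q11 - 36962*Delta**5*p11*p20*q02**4 + 32968*Delta**5*p11*q02**4*q11 + 13632*Delta**5*p20*q02**5 + 33834*Delta**5*q02**5*q11 - 27164*Delta**4*p02**2*p11*p20*q20**2 - 7552*Delta**4*p02**2*p11*q11*q20**2 + 213280*Delta**4*p02**2*p20**3*q20 + 288224*Delta**4*p02**2*p20**2*q11*q20 - 30208*Delta**4*p02**2*p20*q02*q20**2 + 131634*Delta**4*p02**2*p20*q11**2*q20 - 3044*Delta**4*p02**2*q02*q11*q20**2 + 20421*Delta**4*p02**2*q11**3*q20 - 2901*Delta**4*p02*p11**3*q20**2 - 95044*Delta**4*p02*p11**2*p20**2*q20 - 54550*Delta**4*p02*p11**2*p20*q11*q20 - 28690*Delta**4*p02*p11**2*q02*q20**2 - 8224*Delta**4*p02*p11**2*q11**2*q20 - 249074*Delta**4*p02*p11*p20**4 - 356424*Delta**4*p02*p11*p20**3*q11 - 215216*Delta**4*p02*p11*p20**2*q02*q20 - 196779*Delta**4*p02*p11*p20**2*q11**2 - 124544*Delta**4*p02*p11*p20*q02*q11*q20 - 47112*Delta**4*p02*p11*p20*q11**3 - 86688*Delta**4*p02*p11*q02**2*q20**2 - 13418*Delta**4*p02*p11*q02*q11**2*q20 - 3679*Delta**4*p02*p11*q11**4 - 224516*Delta**4*p02*p20**4*q02 - 157728*Delta**4*p02*p20**3*q02*q11 - 41472*Delta**4*p02*p20**2*q02**2*q20 + 17830*Delta**4*p02*p20**2*q02*q11**2 + 33456*Delta**4*p02*p20*q02**2*q11*q20 + 38090*Delta**4*p02*p20*q02*q11**3 - 81824*Delta**4*p02*q02**3*q20**2 + 36036*Delta**4*p02*q02**2*q11**2*q20 + 8240*Delta**4*p02*q02*q11**4 - 304*Delta**4*p11**4*p20*q20 + 111*Delta**4*p11**4*q11*q20 + 5571*Delta**4*p11**3*p20**3 + 1882*Delta**4*p11**3*p20**2*q11 - 10698*Delta**4*p11**3*p20*q02*q20 - 570*Delta**4*p11**3*p20*q11**2 + 2408*Delta**4*p11**3*q02*q11*q20 - 49528*Delta**4*p11**2*p20**3*q02 - 43591*Delta**4*p11**2*p20**2*q02*q11 - 38598*Delta**4*p11**2*p20*q02**2*q20 - 10816*Delta**4*p11**2*p20*q02*q11**2 + 18395*Delta**4*p11**2*q02**2*q11*q20 + 954*Delta**4*p11**2*q02*q11**3 - 113884*Delta**4*p11*p20**3*q02**2 - 57664*Delta**4*p11*p20**2*q02**2*q11 + 8352*Delta**4*p11*p20*q02**3*q20 + 14327*Delta**4*p11*p20*q02**2*q11**2 + 69384*Delta**4*p11*q02**3*q11*q20 + 9318*Delta**4*p11*q02**2*q11**3 + 4608*Delta**4*p20**3*q02**3 + 116956*Delta**4*p20**2*q02**3*q11 + 100996*Delta**4*p20*q02**4*q20 + 102200*Delta**4*p20*q02**3*q11**2 + 87986*Delta**4*q02**4*q11*q20 + 20237*Delta**4*q02**3*q11**3 + 14600*Delta**3*p02**2*p20*q20**3 + 7300*Delta**3*p02**2*q11*q20**3 - 1700*Delta**3*p02*p11**2*q20**3 + 15416*Delta**3*p02*p11*p20**2*q20**2 + 12024*Delta**3*p02*p11*p20*q11*q20**2 - 11560*Delta**3*p02*p11*q02*q20**3 + 4563*Delta**3*p02*p11*q11**2*q20**2 + 337488*Delta**3*p02*p20**4*q20 + 621632*Delta**3*p02*p20**3*q11*q20 + 118512*Delta**3*p02*p20**2*q02*q20**2 + 429272*Delta**3*p02*p20**2*q11**2*q20 + 127768*Delta**3*p02*p20*q02*q11*q20**2 + 131642*Delta**3*p02*p20*q11**3*q20 - 16320*Delta**3*p02*q02**2*q20**3 + 39066*Delta**3*p02*q02*q11**2*q20**2 + 15114*Delta**3*p02*q11**4*q20 - 1681*Delta**3*p11**3*p20*q20**2 + 694*Delta**3*p11**3*q11*q20**2 - 51066*Delta**3*p11**2*p20**3*q20 - 36019*Delta**3*p11**2*p20**2*q11*q20 - 3496*Delta**3*p11**2*p20*q02*q20**2 - 4216*Delta**3*p11**2*p20*q11**2*q20 + 8167*Delta**3*p11**2*q02*q11*q20**2 + 954*Delta**3*p11**2*q11**3*q20 - 89450*Delta**3*p11*p20**5 - 157320*Delta**3*p11*p20**4*q11 - 16576*Delta**3*p11*p20**3*q02*q20 - 107053*Delta**3*p11*p20**3*q11**2 + 51096*Delta**3*p11*p20**2*q02*q11*q20 - 32882*Delta**3*p11*p20**2*q11**3 + 44544*Delta**3*p11*p20*q02**2*q20**2 + 60950*Delta**3*p11*p20*q02*q11**2*q20 - 3679*Delta**3*p11*p20*q11**4 + 43488*Delta**3*p11*q02**2*q11*q20**2 + 13296*Delta**3*p11*q02*q11**3*q20 - 18240*Delta**3*p20**5*q02 + 89506*Delta**3*p20**4*q02*q11 + 200696*Delta**3*p20**3*q02**2*q20 + 173116*Delta**3*p20**3*q02*q11**2 + 411692*Delta**3*p20**2*q02**2*q11*q20 + 111481*Delta**3*p20**2*q02*q11**3 + 126704*Delta**3*p20*q02**3*q20**2 + 244470*Delta**3*p20*q02**2*q11**2*q20 + 31326*Delta**3*p20*q02*q11**4 + 78400*Delta**3*q02**3*q11*q20**2 + 37971*Delta**3*q02**2*q11**3*q20 + 3195*Delta**3*q02*q11**5 + 930*Delta**2*p02*p11*q20**4 + 37328*Delta**2*p02*p20**2*q20**3 + 35688*Delta**2*p02*p20*q11*q20**3 + 1860*Delta**2*p02*q02*q20**4 + 8512*Delta**2*p02*q11**2*q20**3 + 1858*Delta**2*p11**2*p20*q20**3 + 489*Delta**2*p11**2*q11*q20**3 + 56736*Delta**2*p11*p20**3*q20**2 + 67344*Delta**2*p11*p20**2*q11*q20**2 + 14264*Delta**2*p11*p20*q02*q20**3 + 30399*Delta**2*p11*p20*q11**2*q20**2 + 5272*Delta**2*p11*q02*q11*q20**3 + 3978*Delta**2*p11*q11**3*q20**2 + 178900*Delta**2*p20**5*q20 + 422330*Delta**2*p20**4*q11*q20 + 167328*Delta**2*p20**3*q02*q20**2 + 389610*Delta**2*p20**3*q11**2*q20 + 288528*Delta**2*p20**2*q02*q11*q20**2 + 175205*Delta**2*p20**2*q11**3*q20 + 50336*Delta**2*p20*q02**2*q20**3 + 146916*Delta**2*p20*q02*q11**2*q20**2 + 38200*Delta**2*p20*q11**4*q20 + 23208*Delta**2*q02**2*q11*q20**3 + 19287*Delta**2*q02*q11**3*q20**2 + 3195*Delta**2*q11**5*q20 - 1750*Delta*p11*p20*q20**4 - 1800*Delta*p11*q11*q20**4 + 9744*Delta*p20**3*q20**3 + 29616*Delta*p20**2*q11*q20**3 - 2080*Delta*p20*q02*q20**4 + 15478*Delta*p20*q11**2*q20**3 - 2890*Delta*q02*q11*q20**4 + 1553*Delta*q11**3*q20**3 - 3700*p20*q20**5 - 1850*q11*q20**5)
    return num / (18432*Delta**8)

# fmt: on
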
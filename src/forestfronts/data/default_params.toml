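# Reference parameter set of the forest-savanna model
# (average rainfall seasonality and soils).

r_S = 0.09      # 1/y
r_F = 0.20      # 1/y
k_RS = 0.005    # 1/mm
k_RF = 0.003    # 1/mm
a_RS = 0.25
a_RF = 1.54
m_So = 0.023    # 1/y (adult savanna mortality m_To = m_So)
m_Fo = 0.041    # 1/y
a_MS = 0.0
a_MF = -2.15
k_MS = 0.008    # 1/mm
k_MF = 0.008    # 1/mm
Q0 = 0.04       # 1/y
h = 0.85
tau = 2.7       # y
n_fire = 4
Y_c0 = 0.56
k_c = -1.43e-4  # 1/mm
b = 0.46
c_def = 0.092   # 1/y
k_C = 0.0015    # 1/m
D_S = 0.2       # km^2/y
D_F = 0.1       # km^2/y
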
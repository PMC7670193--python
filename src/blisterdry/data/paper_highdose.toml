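# Reference configuration: high-dose (500 mg acetaminophen) oral lyophilizate
# in a cold-form aluminium blister pocket.  All values are the printed
# parameter set of the modeled product; lengths/volumes carry explicit units.

[geometry]
total_length = "40.5 mm"
chord_length = "23.5 mm"
height = "7.2 mm"

[formulation]
label = "high-dose APAP"
fill_volume = "1.52 mL"

[formulation.solids]   # % w/w, water ad 100
drug = 33.00
pva = 3.39
mannitol = 2.76
xanthan = 0.075

[constants]
molecular_weight_water = 18.01528e-3
rho_ice = 918.0
rho_solution = 1018.0
lambda_ice = 2.3
conversion_a = 889200.0
conversion_b = 1.02

[enthalpy]
alpha = 4.68e4
beta = 35.9
gamma = 0.0741
delta = 542.0
epsilon = 124.0

[vapor_pressure]
alpha = 9.550426
beta = 5723.2658
gamma = 3.53068
delta = 0.00728332

[kv]
pressure_range = [10.0, 30.0]

[kv.edge]
alpha = 10.1917
beta = 1.1408
gamma = 0.0614

[kv.center]
alpha = 12.7208
beta = 0.3015
gamma = 0.0261

[rp]
rp0 = 7.05e4
a = 1.92e8
b = -68.30
fit_range_max = "4.5 mm"

[process]
chamber_pressure = "10 Pa"
time_step = "60 s"
collapse_temperature = "-10 C"

[machine]
max_ramp = 1.4              # K/min
setpoint_resolution = 0.1   # K
prediction_interval = "30 s"
shelf_temp_max = "40 C"
shelf_temp_min = "-50 C"

[optimizer]
initial_shelf_temp = "-30 C"

[protocol]                  # traditional ramp-and-hold cycle
start = "-30 C"
hold = "-10 C"
ramp_rate = 0.25            # K/min
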
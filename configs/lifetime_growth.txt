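# antsim run configuration
arena_width = 30.0
arena_height = 30.0
dt = 0.1
duration = 2000.0
hunger_period = 3.0
max_satiety = 15.0
birth_fraction = 0.7
initial_satiety = 8.0
food_energy = 1.0
food_count = 55
eat_radius = 1.5
initial_population = 20
max_population = 60
food_radius = 0.4
organism_radius = 0.5
food_height = 0.8
organism_height = 1.0
vision_width = 10
vision_height = 10
fov = 1.5707963267948966
view_range = 20.0
layer_sizes = 300,24,3
activation = logistic
action_threshold = 0.5
weight_init = 1.0
mutation_a = 0.1
mutation_b = 0.3
mutation_c = 0.02
mutation_d = 0.5
max_speed = 5.0
turn_rate = 1.5
speed_step = 10.0
initial_speed = 0.0
sample_interval = 100
seed = 0
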
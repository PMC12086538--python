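"""Published 50-yr herd-average reference grids.

Rows are breeding-season lengths (2-6 estrus cycles); columns are per-cycle
fertilities from 66% down to 54% in 1% steps. Cows bred are whole cows,
weights whole pounds, revenue thousands of dollars, as published.
"""

FERTILITIES = tuple(round(0.66 - 0.01 * i, 2) for i in range(13))

COWS_BRED = {
    2: (885, 878, 871, 864, 856, 848, 840, 832, 824, 816, 807, 798, 789),
    3: (958, 955, 950, 946, 942, 937, 932, 927, 921, 915, 909, 903, 897),
    4: (983, 981, 979, 976, 973, 970, 967, 964, 960, 956, 952, 948, 943),
    5: (993, 992, 990, 989, 987, 985, 983, 980, 978, 976, 972, 969, 966),
    6: (998, 997, 996, 995, 995, 993, 992, 991, 990, 988, 986, 984, 982),
}

WEANING_WEIGHT = {
    2: (498, 498, 498, 498, 497, 497, 497, 497, 497, 496, 496, 496, 496),
    3: (491, 491, 490, 490, 489, 489, 488, 488, 487, 487, 486, 486, 485),
    4: (486, 485, 484, 483, 482, 481, 480, 479, 479, 478, 477, 476, 475),
    5: (482, 480, 479, 478, 477, 475, 474, 473, 471, 470, 469, 468, 466),
    6: (479, 478, 476, 475, 473, 471, 470, 468, 466, 464, 463, 461, 459),
}

CALF_REVENUE = {
    2: (937, 930, 922, 914, 906, 897, 888, 880, 871, 862, 853, 843, 833),
    3: (1006, 1002, 996, 991, 986, 980, 974, 969, 962, 955, 948, 941, 934),
    4: (1024, 1021, 1017, 1013, 1009, 1005, 1001, 996, 991, 986, 980, 975, 969),
    5: (1028, 1025, 1022, 1019, 1015, 1011, 1007, 1002, 998, 994, 989, 984, 979),
    6: (1030, 1027, 1023, 1020, 1017, 1013, 1009, 1005, 1001, 997, 992, 988, 982),
}
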
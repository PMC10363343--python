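subject,wrkmem,storym,swapped_flag
100307,0.2563,0.2006,0
102816,0.2372,0.1864,0
104012,0.2388,0.2045,0
106521,0.2301,0.1881,0
108323,0.2477,0.175,0
109123,0.259,0.1862,0
116726,0.2235,0.1968,0
133019,0.2497,0.1992,0
140117,0.2349,0.1942,0
146129,0.251,0.1871,0
149741,0.2653,0.1967,0
151526,0.2534,0.1843,0
156334,0.2549,0.1963,0
158136,0.2528,0.1914,0
162026,0.2557,0.1981,0
166438,0.2579,0.2036,0
169040,0.2604,0.1883,1
175540,0.2364,0.1889,0
182840,0.2549,0.187,0
185442,0.238,0.1748,0
191033,0.2458,0.2021,0
191437,0.2373,0.1814,0
192641,0.2477,0.1749,0
195041,0.2562,0.1878,0
200109,0.2378,0.2118,0
204521,0.2449,0.1794,0
205119,0.2504,0.197,0
212318,0.2413,0.1867,0
212823,0.2454,0.2006,0
214524,0.2452,0.2049,0
223929,0.2289,0.2115,0
248339,0.2403,0.1728,0
255639,0.246,0.1714,0
257845,0.2565,0.2003,1
283543,0.2675,0.201,0
293748,0.2587,0.1883,0
353740,0.2471,0.1941,0
433839,0.2485,0.1766,0
512835,0.2546,0.1846,0
555348,0.2528,0.1824,0
568963,0.2376,0.1933,1
599671,0.2382,0.1812,0
601127,0.2503,0.1965,0
660951,0.2488,0.2012,0
662551,0.2379,0.1976,0
665254,0.2509,0.1817,0
667056,0.2392,0.1856,0
679770,0.2308,0.1993,0
706040,0.2086,0.1677,0
707749,0.2122,0.166,0
715950,0.2473,0.1914,0
725751,0.2648,0.1928,0
735148,0.2398,0.2021,0
783462,0.2479,0.1897,0
814649,0.2379,0.1899,0
825048,0.2393,0.1993,0
872764,0.2388,0.1849,0
877168,0.2377,0.1856,0
891667,0.2473,0.1943,0
917255,0.2564,0.2027,0
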
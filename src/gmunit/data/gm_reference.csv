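item_number,item_name,predicted_difficulty,gm_units
2,SUP: BRINGS HANDS TO MIDLINE,14.13,0
6,SUP: R HAND CROSSES MIDLINE,14.13,0
7,SUP: L HAND CROSSES MIDLINE,14.13,0
10,PR: LIFTS HEAD UPRIGHT,21.5,15
22,LIFTS HEAD TO MIDLINE,22.73,18
21,SIT: LIFTS HEAD UPRIGHT,22.73,18
23,SIT: ARMS PROPPING,26.45,26
18,SUP: PULLS TO SITTING,27.66,28
24,SIT: ARMS FREE,36.31,46
25,SIT: WITH TOY,36.31,46
34,SIT: ARMS & FEET FREE,36.31,46
27,SIT: REACH BEHIND TO L,36.31,46
26,SIT: REACH BEHIND TO R,36.31,46
39,4-POINT: MAINTAINS 4PT,37.54,49
30,SIT: LOWERS TO PRONE,39.94,54
52,ON FLOOR: PULL TO STAND AT BENCH,42.28,59
41,PRN: ATTAINS 4PT,42.38,59
40,4-POINT: ATTAINS SIT,42.38,59
32,SIT ON MAT: TO 4PT OVER L SIDE,42.38,59
53,"STD: ARMS FREE, 3 SEC",42.46,59
56,STD: ARMS FREE 10 SEC,42.46,59
31,SIT ON MAT: TO 4PT OVER A SIDE,43.61,62
43,4-POINT: REACHES WITH L,44.82,64
42,4-POINT: REACHES WITH R,44.82,64
44,4-POINT: CRAWLS FORWARD 1.6m,46.03,67
45,4-POINT: CRAWLS RECPRCLLY 1.0m,46.03,67
46,4-POINT: CRAWL UP 4 STEPS,46.03,67
65,STD: CRUISE TO R WITH BENCH,48.35,72
66,STD: CRUISE TO L WITH BENCH,48.35,72
48,SIT ON MAT: ATTAIN HIGH KN ARMS FREE,48.47,72
36,ON FLOOR: ATTAINS SIT SMALL BENCH,49.7,74
37,ON FLOOR: ATTAINS SIT LARGE BENCH,49.7,74
67,STD: WALK WITH HANDS HELD,52.02,79
59,SIT BENCH: ATTAINS STD ARMS FREE,53.35,82
35,STD: ATTAINS SIT,54.56,84
62,"STD: LOWERS TO SIT, ARMS FREE",54.56,84
51,HIGH KN: KN WALK FORWARD,55.73,87
61,HIGH KN: TO STAND L SIDE,55.77,87
60,HIGH KN: TO STAND A SIDE,55.77,87
68,STD 1 HAND HELD: WALK WITH 1 HAND HELD,56.95,89
54,STD: LIFT R FOOT,59.37,95
55,"STD, LIFT L FOOT",59.37,95
63,"STD: TO SQUAT, ARMS FREE",59.4,95
64,STD: PICK UP OBJ ARMS FREE,59.4,95
84,"STD, HOLDING 1 RAIL: UP 4 STEPS",60.58,97
85,STD: DOWN 4 STEPS HLDING RAIL,61.79,100
69,"STD: WALK, HANDS FREE",61.88,100
70,"STD: WALK 10 STEPS, RETURN",64.3,105
72,STD: WALK WITH OBJECT HELD,64.3,105
57,STD: LIFT LFT ARMS FREE,64.3,105
58,STD: LIFT RFT ARMS FREE,64.3,105
71,STD: WALK BACKWARD 10 STEPS,64.3,105
73,STD: WALK BETWEEN LINES,64.3,105
75,"STD: STEP OVER STICK, A FOOT",64.3,105
76,"STD: STEP OVER STICK, L FOOT",64.3,105
74,STD: WALK ALONG STRAIGHT LINE,64.3,105
86,"STD: UP 4 STEPS, NO RAIL",65.51,107
87,"STD: DOWN 4 STEPS, NO RAIL Difficult",66.72,110
78,"STD: KICK BALL, R FOOT",67.93,112
79,"STD: KICK BALL, L FOOT",67.93,112
77,"STD: RUN 4.5m, RETURN",70.37,118
80,STD: JUMP UP 30cm BOTH FEET,71.58,120
81,STD: JUMP FWD 30cm BOTH FEET,71.58,120
88,"STD 6"" STEP: JUMP OFF 15cm STP 2 FEET",71.58,120
82,"STD L FOOT: HOP 10X, R FOOT",72.79,123
83,"STD L FOOT: HOP 10X, L FOOT",72.79,123
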
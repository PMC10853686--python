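item_number,item_name,body_position,movement,support
2,SUP: BRINGS HANDS TO MIDLINE,1,1,1
6,SUP: R HAND CROSSES MIDLINE,1,1,1
7,SUP: L HAND CROSSES MIDLINE,1,1,1
10,PR: LIFTS HEAD UPRIGHT,2,2,2
18,SUP: PULLS TO SITTING,3,2,3
21,SIT: LIFTS HEAD UPRIGHT,3,2,2
22,LIFTS HEAD TO MIDLINE,3,2,2
23,SIT: ARMS PROPPING,3,1,3
24,SIT: ARMS FREE,3,1,5
25,SIT: WITH TOY,3,1,5
26,SIT: REACH BEHIND TO R,3,1,5
27,SIT: REACH BEHIND TO L,3,1,5
30,SIT: LOWERS TO PRONE,3,4,5
31,SIT ON MAT: TO 4PT OVER A SIDE,5,5,5
32,SIT ON MAT: TO 4PT OVER L SIDE,4,5,5
34,SIT: ARMS & FEET FREE,3,1,5
35,STD: ATTAINS SIT,8,11,5
36,ON FLOOR: ATTAINS SIT SMALL BENCH,7,8,5
37,ON FLOOR: ATTAINS SIT LARGE BENCH,7,8,5
39,4-POINT: MAINTAINS 4PT,4,1,5
40,4-POINT: ATTAINS SIT,4,5,5
41,PRN: ATTAINS 4PT,4,5,5
42,4-POINT: REACHES WITH R,5,6,5
43,4-POINT: REACHES WITH L,5,6,5
44,4-POINT: CRAWLS FORWARD 1.6 m,5,7,5
45,4-POINT: CRAWLS RECPRCLLY 1.0 m,5,7,5
46,4-POINT: CRAWL UP 4 STEPS,5,7,5
48,SIT ON MAT: ATTAIN HIGH KN ARMS FREE,6,8,5
51,HIGH KN: KN WALK FORWARD,6,14,5
52,ON FLOOR: PULL TO STAND AT BENCH,8,9,3
53,"STD: ARMS FREE, 3 SEC",8,1,5
54,STD: LIFT R FOOT,11,16,4
55,"STD, LIFT L FOOT",11,16,4
56,STD: ARMS FREE 10 SEC,8,1,5
57,STD: LIFT LFT ARMS FREE,11,16,5
58,STD: LIFT RFT ARMS FREE,11,16,5
59,SIT BENCH: ATTAINS STD ARMS FREE,8,10,5
60,HIGH KN: TO STAND A SIDE,8,12,5
61,HIGH KN: TO STAND L SIDE,8,12,5
62,"STD: LOWERS TO SIT, ARMS FREE",8,11,5
63,"STD: TO SQUAT, ARMS FREE",8,15,5
64,STD: PICK UP OBJ ARMS FREE,8,15,5
65,STD: CRUISE TO R WITH BENCH,9,13,3
66,STD: CRUISE TO L WITH BENCH,9,13,3
67,STD: WALK WITH HANDS HELD,11,14,3
68,STD 1 HAND HELD: WALK WITH 1 HAND HELD,11,14,4
69,"STD: WALK, HANDS FREE",11,14,5
70,"STD: WALK 10 STEPS, RETURN",11,16,5
71,STD: WALK BACKWARD 10 STEPS,11,16,5
72,STD: WALK WITH OBJECT HELD,11,16,5
73,STD: WALK BETWEEN LINES,11,16,5
74,STD: WALK ALONG STRAIGHT LINE,11,16,5
75,"STD: STEP OVER STICK, A FOOT",11,16,5
76,"STD: STEP OVER STICK, L FOOT",11,16,5
77,"STD: RUN 4.5 m, RETURN",12,20,5
78,"STD: KICK BALL, R FOOT",11,19,5
79,"STD: KICK BALL, L FOOT",11,19,5
80,STD: JUMP UP 30 cm BOTH FEET,12,21,5
81,STD: JUMP FWD 30 cm BOTH FEET,12,21,5
82,"STD L FOOT: HOP 10X, R FOOT",12,22,5
83,"STD L FOOT: HOP 10X, L FOOT",12,22,5
84,"STD, HOLDING 1 RAIL: UP 4 STEPS",11,17,4
85,STD: DOWN 4 STEPS HLDING RAIL,11,18,4
86,"STD: UP 4 STEPS, NO RAIL",11,17,5
87,"STD: DOWN 4 STEPS, NO RAIL Difficult",11,18,5
88,"STD 6"" STEP: JUMP OFF 15 cm STP 2 FEET",12,21,5
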
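"lat","lon","brg","dist","dest_lon","dest_lat"
53.7800227641128,61.1977767804638,69.0903893485665,1752.88034179248,88.004230645421,59.4061220349453
-11.2480001384392,-80.3352236934006,181.581050315872,91.63406745065,-80.3584403465769,-12.0717713721499
-42.2732443362474,-106.857151133008,274.982528463006,4562.29620407103,-160.625393653429,-38.7097329953524
-47.3276453418657,-107.051304643974,249.720793459564,951.916822022758,-119.250058080814,-50.2947758036779
-28.1875670352019,-41.0391061659902,195.859507787973,3627.87707267562,-53.8820696268934,-59.5719195888152
32.121146840509,117.988293315284,237.271401453763,2881.21848711744,93.8273781154,18.1118709494813
-17.593141188845,-0.654114633798599,168.742216816172,2723.18024724955,4.9124453743519,-41.6120689402258
51.9268750725314,98.7990950001404,173.449994036928,1806.98970629601,101.394421026204,35.7822994601976
-36.7558966996148,115.077716470696,121.342895440757,4129.25459912512,161.799969278002,-56.0721339563697
-4.49859676416963,-14.6526859467849,152.829468604177,971.376968012191,-10.6172385337488,-12.2704156692328
-36.1077115521766,101.82177699171,103.325447151437,2012.05419743201,124.236382181987,-40.2782449247518
-29.5375188020989,-40.1393591752276,216.428951555863,2456.76364167593,-57.0411258728942,-47.3143810406698
30.0093140336685,88.2984187081456,302.667237482965,2509.85746589722,64.6892897964002,42.1925881184762
-44.4068304169923,-21.4962952630594,223.501337170601,1965.85007539252,-40.923229202726,-57.2306680102861
-5.12074528960511,137.434025048278,48.4385829046369,3234.07539038453,159.369860439548,14.1747246755611
-45.682921577245,-61.3581292843446,204.380074627697,1751.95972122019,-72.2589404278131,-60.0336904048432
6.67324537644163,-141.926508466713,159.633479174227,4782.71521193674,-126.164655886844,-33.6498730792944
-54.0424940083176,107.538286987692,157.671152176335,261.423120542895,109.10109223951,-56.2172446279572
53.4310799767263,135.481915026903,224.502203715965,3838.66761182435,102.713074683673,28.809202033351
-20.1756715495139,158.608775231987,335.755203086883,1058.66171101807,154.540463867723,-11.4946365780092
15.3393836109899,24.8434202326462,319.857329986989,3439.53509506537,2.18187803103464,38.9854564098078
-22.5254441075958,74.8270288109779,316.274601984769,2011.03037981084,61.7900654126309,-9.45566736820148
54.6374063263647,93.179932218045,87.1837011538446,339.356886222959,98.4565932552901,54.7873585472526
44.6623452287167,43.4386721812189,266.923366952688,3694.45715184556,-2.51109457707213,42.8791043903293
53.7613058462739,75.8163761021569,139.556272812188,3143.01965449704,101.306365541786,32.2497621271961
-47.7789686620235,-38.4773651696742,28.4226259589195,3164.38477437478,-21.6158457959927,-22.7512801323189
13.9742634329014,-114.651135527529,34.1407980211079,2851.29488460952,-98.6949005900092,35.197402004833
-1.04774550534785,-106.342383651063,274.371383199468,3957.13650431717,-141.830070399089,1.66476163884903
51.8126854184084,-36.9751787930727,125.24184926413,961.219282064121,-26.1315908485883,46.8245854349548
-15.1557067735121,-76.8735887017101,150.036015221849,4171.80777851027,-54.3807964309582,-47.6590059558082
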